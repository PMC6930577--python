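"""Agreement criteria between back-calculated and experimental data.

Three error-aware criteria complement the plain RMS deviation:

* quality ``n/chi2`` with chi2 = sum(((theo-exp)/err)^2): above 1 when the
  calculation lies, on average, within the experimental error bounds;
* outlier criterion ``1/chi2_min`` = 1 / max_i((theo_i-exp_i)/err_i)^2:
  above 1 iff even the worst datum is within its error;
* fidelity ``F`` = fraction of data whose deviation is within its error
  (the boundary |dev| == err counts as valid).

Because the deviations are normalized by the experimental errors, data of
different physical units (Hz, Å) can be pooled: the report on concatenated
types is recomputed from the pooled raw vectors, never by averaging
averages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TypeQuality:
    """Criteria for one data type (native units for the RMS)."""

    n: int
    chi2: float
    quality: float  # n/chi2, inf when chi2 == 0
    outlier_criterion: float  # 1/chi2_min
    fidelity: float
    rms: float
    outlier_ids: list = field(default_factory=list)


@dataclass
class QualityReport:
    """Per-type and pooled criteria."""

    per_type: dict
    overall: TypeQuality

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, tq in {**self.per_type, "overall": self.overall}.items():
            rows.append(
                {
                    "type": name,
                    "n": tq.n,
                    "chi2": tq.chi2,
                    "n_over_chi2": tq.quality,
                    "inv_chi2_min": tq.outlier_criterion,
                    "fidelity": tq.fidelity,
                    "rms": tq.rms,
                    "outliers": ",".join(tq.outlier_ids),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self):
        lines = [
            f"{'type':<12}{'n':>4}{'n/chi2':>10}{'1/chi2min':>11}{'F':>8}{'rms':>10}  outliers"
        ]
        for name, tq in {**self.per_type, "overall": self.overall}.items():
            q = "inf" if np.isinf(tq.quality) else f"{tq.quality:.2f}"
            o = "inf" if np.isinf(tq.outlier_criterion) else f"{tq.outlier_criterion:.3f}"
            lines.append(
                f"{name:<12}{tq.n:>4}{q:>10}{o:>11}{tq.fidelity:>8.2f}{tq.rms:>10.3f}  "
                + ",".join(tq.outlier_ids)
            )
        return "\n".join(lines)


def _validated(theo, exp, err):
    theo = np.asarray(theo, dtype=float)
    exp = np.asarray(exp, dtype=float)
    err = np.asarray(err, dtype=float)
    if theo.size == 0:
        raise ValueError("empty data: criteria undefined")
    if not (theo.shape == exp.shape == err.shape):
        raise ValueError("theo, exp and err must have equal lengths")
    if np.any(err <= 0):
        raise ValueError("errors must be positive")
    return theo, exp, err


def chi2_quality(theo, exp, err):
    """Return (chi2, n/chi2); a perfect fit reports quality = +inf."""
    theo, exp, err = _validated(theo, exp, err)
    dev = (theo - exp) / err
    chi2 = float(np.sum(dev * dev))
    quality = np.inf if chi2 == 0.0 else len(dev) / chi2
    return chi2, quality


def outlier_criterion(theo, exp, err):
    """1/chi2_min: reciprocal squared normalized deviation of the worst datum."""
    theo, exp, err = _validated(theo, exp, err)
    worst = float(np.max(((theo - exp) / err) ** 2))
    return np.inf if worst == 0.0 else 1.0 / worst


def fidelity(theo, exp, err, ids=None):
    """Ratio of valid data F = (n - n_outliers)/n and the outlier id list.

    A datum is an outlier iff |theo - exp| strictly exceeds its error.
    """
    theo, exp, err = _validated(theo, exp, err)
    bad = np.abs(theo - exp) > err
    if ids is None:
        ids = [str(i) for i in range(len(theo))]
    flagged = [ids[i] for i in np.nonzero(bad)[0]]
    return float((len(theo) - bad.sum()) / len(theo)), flagged


def q_factor(calc, obs):
    """Q = rms(calc - obs) / rms(obs), the usual RDC quality-of-fit ratio."""
    calc = np.asarray(calc, dtype=float)
    obs = np.asarray(obs, dtype=float)
    denom = np.sqrt(np.mean(obs * obs))
    if denom == 0.0:
        raise ZeroDivisionError("all-zero observed vector: Q undefined")
    return float(np.sqrt(np.mean((calc - obs) ** 2)) / denom)


def type_quality(theo, exp, err, ids=None) -> TypeQuality:
    theo, exp, err = _validated(theo, exp, err)
    chi2, qual = chi2_quality(theo, exp, err)
    fid, flagged = fidelity(theo, exp, err, ids)
    return TypeQuality(
        n=len(theo),
        chi2=chi2,
        quality=qual,
        outlier_criterion=outlier_criterion(theo, exp, err),
        fidelity=fid,
        rms=float(np.sqrt(np.mean((theo - exp) ** 2))),
        outlier_ids=flagged,
    )


def build_report(groups: dict) -> QualityReport:
    """Assemble a report from {type: (theo, exp, err, ids)} groups.

    The overall block pools the raw normalized vectors of all types.
    """
    per_type = {}
    all_theo, all_exp, all_err, all_ids = [], [], [], []
    for name, (theo, exp, err, ids) in groups.items():
        if len(np.atleast_1d(theo)) == 0:
            continue
        per_type[name] = type_quality(theo, exp, err, ids)
        all_theo.extend(np.atleast_1d(theo))
        all_exp.extend(np.atleast_1d(exp))
        all_err.extend(np.atleast_1d(err))
        all_ids.extend(ids if ids is not None else [])
    overall = type_quality(all_theo, all_exp, all_err, all_ids or None)
    return QualityReport(per_type=per_type, overall=overall)


def trajectory_report(ensemble, constraints) -> QualityReport:
    """Quality report from snapshot-averaged observables of a run.

    The back-calculated value of each constraint is the mean over the
    recorded snapshots of its memory-averaged observable (the zz tensor
    component for RDCs).
    """
    import numpy as np

    groups = {}

    def series_mean(cid, extract=lambda v: v):
        vals = [extract(s.observables[cid]) for s in ensemble.snapshots]
        return float(np.mean(vals))

    one = [c for c in constraints.rdc if c.kind in ("one-bond", "methyl")]
    far = [c for c in constraints.rdc if c.kind == "long-range"]
    for name, group in (("1D", one), ("nD", far)):
        if group:
            groups[name] = (
                [series_mean(c.id, lambda v: v[2, 2]) for c in group],
                [c.d_exp for c in group],
                [c.error for c in group],
                [c.id for c in group],
            )
    if constraints.noe:
        groups["NOE"] = (
            [series_mean(c.id) for c in constraints.noe],
            [c.target for c in constraints.noe],
            [c.error for c in constraints.noe],
            [c.id for c in constraints.noe],
        )
    if constraints.j:
        groups["3J"] = (
            [series_mean(c.id) for c in constraints.j],
            [c.j_exp for c in constraints.j],
            [c.error for c in constraints.j],
            [c.id for c in constraints.j],
        )
    if not groups:
        raise ValueError("no constraints to report on")
    return build_report(groups)
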