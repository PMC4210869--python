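"""Comparison of functional and sequence distance structures.

The central question: do receptors diverge in ligand specificity at the
rate their sequences diverge?  Under neutral coupling the two pairwise
distance structures are proportional, so a scatter of (functional,
sequence) distances per receptor pair hugs a regression line.  A pair
whose sequence distance sits *above* the line's confidence band has a
functional distance smaller than its sequence divergence predicts —
the signature of positive pleiotropy, e.g. one peptide retaining potency
on a diverged partner's receptor.  Pairs below the band are more
functionally specialized than expected (negative pleiotropy).

Functional distances are Euclidean distances between receptor rows of
the ligand-activity matrix.  Both distance structures are normalized to
a maximum of 1 before comparison.  The regression is ordinary least
squares of sequence distance (y) on functional distance (x); the band
is the 95% confidence interval of the mean response.  Because a strong
outlier inflates the residual variance and can mask itself, the default
flagging rule refits the regression leaving each point out in turn.

Cross-activity need not be reciprocal: ligand A may act on receptor B's
partner while B's ligand ignores A's receptor.  The asymmetry score
formalizes this as a signed difference of best cross-activities.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist
from skbio import DistanceMatrix

from .activity_matrix import ActivityMatrix


def functional_distance_matrix(activity: ActivityMatrix) -> DistanceMatrix:
    """Euclidean distances between receptor activity profiles."""
    scores = activity.scores
    if len(scores) < 2:
        raise ValueError("need at least 2 receptors for a distance matrix")
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = [
            (r, l)
            for r, row in scores.iterrows()
            for l, v in row.items()
            if not np.isfinite(v)
        ]
        raise ValueError(f"activity matrix has missing cells: {bad}")
    return DistanceMatrix(squareform(pdist(values, metric="euclidean")),
                          ids=list(scores.index))


@dataclass
class PairPoint:
    """One receptor pair's (functional, sequence) relative distances."""

    pair: tuple[str, str]
    func_dist: float
    seq_dist: float
    seq_se: float | None = None


def assemble_pairs(
    seq_rel: DistanceMatrix,
    func_rel: DistanceMatrix,
    seq_se: DistanceMatrix | None = None,
) -> list[PairPoint]:
    """Pair up the two relative distance structures, one point per pair.

    Both matrices must be over the same receptors and normalized so the
    maximum off-diagonal distance is 1.  Bootstrap SEs for the sequence
    distances are carried along when provided.
    """
    if set(seq_rel.ids) != set(func_rel.ids):
        raise ValueError(
            f"label mismatch between distance matrices: "
            f"{sorted(set(seq_rel.ids) ^ set(func_rel.ids))}"
        )
    for name, dm in (("sequence", seq_rel), ("functional", func_rel)):
        if not np.isclose(dm.data.max(), 1.0):
            raise ValueError(
                f"{name} distances are not normalized to max 1 "
                f"(max = {dm.data.max():g}); apply normalize_distances first"
            )
    labels = sorted(seq_rel.ids)
    points = []
    for a, b in itertools.combinations(labels, 2):
        points.append(
            PairPoint(
                pair=(a, b),
                func_dist=float(func_rel[a, b]),
                seq_dist=float(seq_rel[a, b]),
                seq_se=float(seq_se[a, b]) if seq_se is not None else None,
            )
        )
    return points


@dataclass
class RegressionFit:
    """OLS fit of sequence distance on functional distance with CI band."""

    slope: float
    intercept: float
    level: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def ci_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Confidence limits for the mean response at ``x``."""
        x = np.asarray(x, dtype=float)
        yhat = self.predict(x)
        df = self.n - 2
        tcrit = t_dist.ppf(0.5 + self.level / 2.0, df)
        half = tcrit * self.residual_sd * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )
        return yhat - half, yhat + half


def fit_regression(points: list[PairPoint], level: float = 0.95) -> RegressionFit:
    """OLS of sequence distance (y) on functional distance (x).

    The confidence band is for the mean response, using the t
    distribution with n - 2 degrees of freedom.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 pair points for a regression")
    x = np.array([p.func_dist for p in points])
    y = np.array([p.seq_dist for p in points])
    if np.ptp(x) == 0:
        raise ValueError("functional distances are all equal; regression degenerate")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        level=level,
        n=len(points),
        residual_sd=resid_sd,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


@dataclass
class Outlier:
    """A pair flagged outside the regression confidence band."""

    pair: tuple[str, str]
    direction: str  # "positive_pleiotropy" or "negative_pleiotropy"
    residual: float  # observed y minus the violated band limit
    lower: float
    upper: float


def detect_pleiotropy_outliers(
    points: list[PairPoint],
    fit: RegressionFit | None = None,
    mode: str = "leave_one_out",
    level: float = 0.95,
    se_z: float = 2.0,
    atol: float = 1e-6,
) -> list[Outlier]:
    """Flag pairs lying outside the regression confidence band.

    ``positive_pleiotropy``: sequence distance above the upper limit —
    the pair is functionally closer than its sequences predict.
    ``negative_pleiotropy``: below the lower limit.  In the default
    ``leave_one_out`` mode the band for each point comes from a refit
    excluding that point, so a strong outlier cannot inflate the band
    and mask itself; ``mode='full'`` evaluates all points against the
    single full-data fit.

    When a point carries a bootstrap SE for its sequence distance, its
    whole error bar (``se_z`` standard errors, default 2) must clear the
    band before the pair is flagged — the numerical equivalent of
    judging the scatter plot with error bars by eye, which keeps
    alignment-sampling jitter from producing spurious calls.  Points
    without SEs are compared to the band directly.  ``atol`` guards
    exactly-collinear input against floating-point flags.
    """
    if mode not in ("leave_one_out", "full"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    outliers = []
    for i, p in enumerate(points):
        if mode == "leave_one_out":
            rest = points[:i] + points[i + 1 :]
            try:
                f = fit_regression(rest, level=level)
            except ValueError:
                continue
        else:
            f = fit if fit is not None else fit_regression(points, level=level)
        lo, hi = f.ci_band(p.func_dist)
        lo, hi = float(lo), float(hi)
        margin = atol + (se_z * p.seq_se if p.seq_se is not None else 0.0)
        if p.seq_dist > hi + margin:
            outliers.append(
                Outlier(p.pair, "positive_pleiotropy", p.seq_dist - hi, lo, hi)
            )
        elif p.seq_dist < lo - margin:
            outliers.append(
                Outlier(p.pair, "negative_pleiotropy", p.seq_dist - lo, lo, hi)
            )
    return outliers


def asymmetry_matrix(
    activity: ActivityMatrix, authentic_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Signed asymmetry of cross-activities between receptor pairs.

    ``cross(i -> j)`` is the best (minimum) activity score that any of
    receptor i's authentic ligands achieves on receptor j — how strongly
    i's own ligands act across on j.  The asymmetry score is
    ``cross(i -> j) - cross(j -> i)``: antisymmetric, zero when the
    cross-activities are reciprocal, negative when i's ligands act on j
    more strongly than j's act on i (scores are potency losses, lower =
    stronger).
    """
    receptors = activity.receptors
    for r in receptors:
        if r not in authentic_map or not authentic_map[r]:
            raise ValueError(f"receptor {r!r} missing from authentic-ligand map")
        for lig in authentic_map[r]:
            if lig not in activity.ligands:
                raise ValueError(
                    f"authentic ligand {lig!r} of receptor {r!r} absent from matrix"
                )
    cross = pd.DataFrame(0.0, index=receptors, columns=receptors)
    for i in receptors:
        for j in receptors:
            cross.loc[i, j] = min(
                activity.scores.loc[j, lig] for lig in authentic_map[i]
            )
    asym = cross - cross.T
    return asym


@dataclass
class CoevolutionReport:
    """Full functional-vs-sequence comparison for a receptor panel."""

    points: list[PairPoint]
    fit: RegressionFit
    outliers: list[Outlier]
    asymmetry: pd.DataFrame
    outlier_mode: str = "leave_one_out"
    metadata: dict = field(default_factory=dict)

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "receptor_i": [p.pair[0] for p in self.points],
                "receptor_j": [p.pair[1] for p in self.points],
                "func_dist": [p.func_dist for p in self.points],
                "seq_dist": [p.seq_dist for p in self.points],
                "seq_se": [p.seq_se for p in self.points],
            }
        )

    def to_json(self, path=None) -> str:
        payload = {
            "regression": {
                "slope": self.fit.slope,
                "intercept": self.fit.intercept,
                "level": self.fit.level,
                "n_points": self.fit.n,
                "residual_sd": self.fit.residual_sd,
                "ci_type": "mean_response",
            },
            "outlier_mode": self.outlier_mode,
            "points": self.points_frame().to_dict(orient="records"),
            "outliers": [
                {
                    "pair": list(o.pair),
                    "direction": o.direction,
                    "residual": o.residual,
                    "band": [o.lower, o.upper],
                }
                for o in self.outliers
            ],
            "asymmetry": {
                i: {j: float(self.asymmetry.loc[i, j]) for j in self.asymmetry.columns}
                for i in self.asymmetry.index
            },
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compare_distance_structures(
    seq_rel: DistanceMatrix,
    func_rel: DistanceMatrix,
    activity: ActivityMatrix,
    authentic_map: dict[str, list[str]],
    seq_se: DistanceMatrix | None = None,
    level: float = 0.95,
    outlier_mode: str = "leave_one_out",
) -> CoevolutionReport:
    """Assemble pairs, fit the regression, flag outliers, score asymmetry."""
    points = assemble_pairs(seq_rel, func_rel, seq_se=seq_se)
    fit = fit_regression(points, level=level)
    outliers = detect_pleiotropy_outliers(points, fit=fit, mode=outlier_mode,
                                          level=level)
    asym = asymmetry_matrix(activity, authentic_map)
    return CoevolutionReport(
        points=points, fit=fit, outliers=outliers, asymmetry=asym,
        outlier_mode=outlier_mode,
    )


def plot_coevolution(report: CoevolutionReport, path) -> None:
    """Scatter of sequence vs functional distance with regression band.

    Error bars show bootstrap SEs of the sequence distances; flagged
    pairs are labeled.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = report.points_frame()
    fig, ax = plt.subplots(figsize=(6, 5))
    xs = np.linspace(0, max(1.0, pts["func_dist"].max()), 100)
    lo, hi = report.fit.ci_band(xs)
    ax.fill_between(xs, lo, hi, alpha=0.25, color="C0",
                    label=f"{report.fit.level:.0%} CI (mean)")
    ax.plot(xs, report.fit.predict(xs), color="C0")
    yerr = pts["seq_se"] if pts["seq_se"].notna().all() else None
    ax.errorbar(pts["func_dist"], pts["seq_dist"], yerr=yerr, fmt="o",
                color="k", ecolor="gray", capsize=2)
    flagged = {o.pair for o in report.outliers}
    for _, row in pts.iterrows():
        if (row["receptor_i"], row["receptor_j"]) in flagged:
            ax.annotate(
                f"{row['receptor_i']}-{row['receptor_j']}",
                (row["func_dist"], row["seq_dist"]),
                textcoords="offset points", xytext=(4, 4), color="C3",
            )
    ax.set_xlabel("relative distance (ligand specificity)")
    ax.set_ylabel("relative distance (amino acid sequence)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
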