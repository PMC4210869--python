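"""Four-parameter logistic (4PL) dose-response analysis.

Raw observations are luminescence readings from receptor-expressing cells
challenged with serial ligand dilutions.  Per receptor, readings are
normalized to the top-plateau response of a reference (most potent
authentic) ligand; each (receptor, ligand) series is then fit with the
four-parameter logistic curve on log-transformed concentration::

    R(c) = bottom + (top - bottom) / (1 + 10 ** (hill * (log10 EC50 - log10 c)))

EC50 is the concentration (nM throughout) giving the half-maximal
response.  A series counts as a *responder* only if the fit converged,
its dynamic range (top - bottom) exceeds a configurable fraction of the
receptor's reference dynamic range, its EC50 lies within a decade of the
tested concentration range, and the sigmoid fits no worse than a flat
line.  Non-responders keep a NaN sentinel in the EC50 matrix; the
downstream activity transform assigns them its cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: canonical plate-reading column order (concentrations in nM)
PLATE_COLUMNS = ["receptor", "ligand", "conc_nM", "replicate", "luminescence"]

#: sentinel for a fitted cell with no detectable response
NON_RESPONDER = np.nan


def four_pl(conc_nM, bottom, top, log10_ec50_nM, hill):
    """Four-parameter logistic response at concentration ``conc_nM``."""
    logc = np.log10(conc_nM)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_ec50_nM - logc)))


@dataclass
class DoseResponseCurve:
    """One fitted (receptor, ligand) dose-response series."""

    receptor: str
    ligand: str
    bottom: float
    top: float
    log10_ec50_nM: float
    hill: float
    rss: float
    converged: bool
    responder: bool
    n_points: int = 0

    @property
    def ec50_nM(self) -> float:
        return 10.0 ** self.log10_ec50_nM


def _validate_plate(readings: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in readings.columns]
    if missing:
        raise ValueError(f"plate data missing columns: {missing}")
    if (readings["conc_nM"] <= 0).any():
        raise ValueError("concentrations must be strictly positive (nM)")
    if not np.isfinite(readings["luminescence"]).all():
        raise ValueError("non-finite luminescence readings present")
    return readings


def normalize_luminescence(
    readings: pd.DataFrame, reference: dict[str, str] | tuple[str, str]
) -> pd.DataFrame:
    """Normalize luminescence per receptor to a reference ligand's plateau.

    ``reference`` maps each receptor to its reference ligand (the most
    potent authentic ligand); a single ``(receptor, ligand)`` tuple is
    accepted for one-receptor data.  For each receptor, every reading is
    divided by the mean reading of the reference ligand at its highest
    tested concentration, so the reference's top plateau maps to 1.0.
    """
    _validate_plate(readings)
    if isinstance(reference, tuple):
        reference = {reference[0]: reference[1]}
    out = []
    for receptor, grp in readings.groupby("receptor", sort=False):
        if receptor not in reference:
            raise ValueError(f"no reference ligand specified for receptor {receptor!r}")
        ref_ligand = reference[receptor]
        ref = grp[grp["ligand"] == ref_ligand]
        if ref.empty:
            raise ValueError(
                f"reference series ({receptor!r}, {ref_ligand!r}) absent from plate"
            )
        plateau = ref.loc[ref["conc_nM"] == ref["conc_nM"].max(), "luminescence"].mean()
        if plateau == 0:
            raise ValueError(
                f"reference plateau is zero for receptor {receptor!r}; cannot normalize"
            )
        grp = grp.copy()
        grp["luminescence"] = grp["luminescence"] / plateau
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def fit_4pl(
    conc_nM,
    response,
    *,
    receptor: str = "",
    ligand: str = "",
    reference_range: float | None = None,
    min_span_fraction: float = 0.2,
    ec50_range_factor: float = 10.0,
) -> DoseResponseCurve:
    """Least-squares 4PL fit of one dose-response series.

    All replicate points are fit jointly.  Initialization: bottom/top from
    the observed extremes, log10 EC50 at the tested concentration nearest
    the half-maximal mean response, hill = 1; the hill slope is bounded to
    [0.1, 10] and log10 EC50 to two decades beyond the tested range.

    ``reference_range`` is the receptor's reference dynamic range used for
    the responder call; when omitted the series' own observed range is
    used.  The responder flag additionally requires the EC50 to fall
    within ``[min_conc / f, max_conc * f]`` (``f = ec50_range_factor``)
    and the sigmoid's RSS not to exceed the flat model's.
    """
    conc = np.asarray(conc_nM, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("concentration and response arrays differ in shape")
    n_conc = np.unique(conc).size
    if n_conc < 4:
        raise ValueError(
            f"need >=4 distinct concentrations to fit a 4PL curve, got {n_conc}"
        )
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive (nM)")

    logc = np.log10(conc)
    ymin, ymax = float(y.min()), float(y.max())
    span = ymax - ymin
    flat_rss = float(np.sum((y - y.mean()) ** 2))

    # init: EC50 at the tested concentration nearest half-maximal response
    means = pd.Series(y).groupby(logc).mean()
    half = (ymin + ymax) / 2.0
    log_ec50_0 = float(means.index[np.argmin(np.abs(means.values - half))])
    p0 = [ymin, ymax, log_ec50_0, 1.0]
    lo = [ymin - max(span, 1e-9), ymin - max(span, 1e-9), logc.min() - 2.0, 0.1]
    hi = [ymax + max(span, 1e-9), ymax + max(span, 1e-9), logc.max() + 2.0, 10.0]

    def model(logc_, bottom, top, log_ec50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logc_)))

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, logc, y, p0=p0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
            )
        bottom, top, log_ec50, hill = (float(v) for v in popt)
        rss = float(np.sum((model(logc, *popt) - y) ** 2))
    except (RuntimeError, ValueError):
        converged = False
        bottom, top, log_ec50, hill = float(p0[0]), float(p0[1]), p0[2], 1.0
        rss = flat_rss

    ref_range = span if reference_range is None else reference_range
    ec50 = 10.0 ** log_ec50
    responder = (
        converged
        and (top - bottom) > min_span_fraction * ref_range
        and conc.min() / ec50_range_factor <= ec50 <= conc.max() * ec50_range_factor
        and rss <= flat_rss + 1e-12
    )
    return DoseResponseCurve(
        receptor=receptor,
        ligand=ligand,
        bottom=bottom,
        top=top,
        log10_ec50_nM=log_ec50,
        hill=hill,
        rss=rss,
        converged=converged,
        responder=responder,
        n_points=y.size,
    )


@dataclass
class EC50Matrix:
    """Receptors-by-ligands EC50 estimates with responder bookkeeping.

    ``ec50_nM`` holds NaN for non-responding cells; ``missing`` lists
    (receptor, ligand) cells absent from the input data; ``warnings``
    lists receptors none of whose authentic ligands responded.
    """

    ec50_nM: pd.DataFrame
    responder: pd.DataFrame
    curves: dict[tuple[str, str], DoseResponseCurve] = field(default_factory=dict)
    missing: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def receptors(self) -> list[str]:
        return list(self.ec50_nM.index)

    @property
    def ligands(self) -> list[str]:
        return list(self.ec50_nM.columns)


def estimate_ec50_matrix(
    dataset: pd.DataFrame,
    authentic_map: dict[str, list[str]],
    *,
    normalize: bool = True,
    min_span_fraction: float = 0.2,
) -> EC50Matrix:
    """Fit every (receptor, ligand) series and assemble the EC50 matrix.

    The reference ligand per receptor is the authentic ligand with the
    most potent fitted EC50 (fit on raw readings); readings are then
    normalized to its plateau and every cell fit jointly across
    replicates.  Receptors whose authentic ligands all fail to respond
    are flagged in ``warnings`` rather than raising.
    """
    _validate_plate(dataset)
    receptors = list(dict.fromkeys(dataset["receptor"]))
    ligands = list(dict.fromkeys(dataset["ligand"]))
    for receptor in receptors:
        if receptor not in authentic_map:
            raise ValueError(f"receptor {receptor!r} missing from authentic-ligand map")

    grouped = {
        key: grp for key, grp in dataset.groupby(["receptor", "ligand"], sort=False)
    }

    # Pass 1: reference = most potent responding authentic ligand per receptor.
    reference: dict[str, str] = {}
    ref_ranges: dict[str, float] = {}
    notes: list[str] = []
    for receptor in receptors:
        best = None
        for ligand in authentic_map[receptor]:
            grp = grouped.get((receptor, ligand))
            if grp is None:
                continue
            curve = fit_4pl(
                grp["conc_nM"], grp["luminescence"],
                receptor=receptor, ligand=ligand,
                min_span_fraction=min_span_fraction,
            )
            if curve.responder and (best is None or curve.ec50_nM < best.ec50_nM):
                best = curve
        if best is None:
            notes.append(
                f"receptor {receptor!r}: no authentic ligand produced a response"
            )
            # fall back: normalize to the first authentic ligand present, if any
            present = [
                l for l in authentic_map[receptor] if (receptor, l) in grouped
            ]
            if present:
                reference[receptor] = present[0]
        else:
            reference[receptor] = best.ligand
            ref_ranges[receptor] = best.top - best.bottom

    if normalize and set(reference) >= set(receptors):
        data = normalize_luminescence(dataset, reference)
        grouped = {
            key: grp for key, grp in data.groupby(["receptor", "ligand"], sort=False)
        }
        for receptor, ligand in reference.items():
            grp = grouped[(receptor, ligand)]
            curve = fit_4pl(
                grp["conc_nM"], grp["luminescence"],
                receptor=receptor, ligand=ligand,
                min_span_fraction=min_span_fraction,
            )
            ref_ranges[receptor] = curve.top - curve.bottom

    # Pass 2: fit every cell.
    ec50 = pd.DataFrame(np.nan, index=receptors, columns=ligands)
    resp = pd.DataFrame(False, index=receptors, columns=ligands)
    curves: dict[tuple[str, str], DoseResponseCurve] = {}
    missing: list[tuple[str, str]] = []
    for receptor in receptors:
        for ligand in ligands:
            grp = grouped.get((receptor, ligand))
            if grp is None:
                missing.append((receptor, ligand))
                continue
            curve = fit_4pl(
                grp["conc_nM"], grp["luminescence"],
                receptor=receptor, ligand=ligand,
                reference_range=ref_ranges.get(receptor),
                min_span_fraction=min_span_fraction,
            )
            curves[(receptor, ligand)] = curve
            resp.loc[receptor, ligand] = curve.responder
            if curve.responder:
                ec50.loc[receptor, ligand] = curve.ec50_nM

    return EC50Matrix(
        ec50_nM=ec50, responder=resp, curves=curves, missing=missing, warnings=notes
    )
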