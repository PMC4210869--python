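"""Capped, normalized log-EC50 ligand-activity matrices.

The ligand-activity matrix summarizes a receptor panel's specificity: per
cell, the log10 EC50 (nM) is capped at a maximum value (default 4, i.e.
an EC50 of 10^4 nM) to blunt artifacts from extremely weak responses;
non-responders are assigned the cap outright.  Each row is then
normalized to its most potent ligand.  Two normalization modes exist:

* ``log_difference`` (default): score = log10 EC50(test) - log10 EC50(lowest),
  i.e. potency loss in log10 units relative to the best ligand.  The best
  ligand scores 0 and rows are invariant to a uniform potency rescale.
* ``ratio_of_logs``: score = log10 EC50(test) / log10 EC50(lowest).  This
  literal ratio is undefined when the best EC50 is 1 nM (log = 0) and
  flips sign below it; it is retained only for sensitivity analysis.

Low score = high activity.  In heatmaps, high activity renders red and
low activity green.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import EC50Matrix

_MODES = ("log_difference", "ratio_of_logs")

#: default log10-nM cap: EC50s above 10^4 nM carry no extra information
DEFAULT_CAP = 4.0


@dataclass
class ActivityMatrix:
    """Receptors-by-ligands normalized activity scores."""

    scores: pd.DataFrame
    mode: str
    cap: float

    @property
    def receptors(self) -> list[str]:
        return list(self.scores.index)

    @property
    def ligands(self) -> list[str]:
        return list(self.scores.columns)

    def to_csv(self, path) -> None:
        """Write the matrix with a metadata header line."""
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode} cap={self.cap:g} units=log10(EC50/nM)\n")
            self.scores.to_csv(fh, index_label="receptor")


def build_activity_matrix(
    ec50_matrix: EC50Matrix | pd.DataFrame,
    cap: float = DEFAULT_CAP,
    mode: str = "log_difference",
) -> ActivityMatrix:
    """Transform an EC50 matrix into the normalized ligand-activity matrix.

    Per cell, ``x = min(log10 EC50_nM, cap)``, with non-responders (NaN)
    assigned ``x = cap``; the cap is applied before row normalization.
    Per row, the normalizer ``x_lowest`` is the row minimum — by
    construction the most potent (authentic) ligand.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {_MODES}")
    ec50 = ec50_matrix.ec50_nM if isinstance(ec50_matrix, EC50Matrix) else ec50_matrix
    values = ec50.to_numpy(dtype=float)
    no_response = ~np.isfinite(values)
    if no_response.all(axis=1).any():
        bad = [r for r, row in zip(ec50.index, no_response) if row.all()]
        raise ValueError(
            f"receptor(s) with no finite EC50 in any cell: {bad}; "
            "cannot identify the most potent ligand"
        )
    with np.errstate(divide="ignore"):
        x = np.where(no_response, cap, np.minimum(np.log10(values), cap))
    x_lowest = x.min(axis=1, keepdims=True)
    if mode == "log_difference":
        scores = x - x_lowest
    else:
        if np.any(x_lowest == 0):
            bad = [r for r, v in zip(ec50.index, x_lowest.ravel()) if v == 0]
            raise ValueError(
                f"ratio_of_logs undefined for receptor(s) {bad} whose lowest "
                "EC50 is 1 nM (log10 = 0); use mode='log_difference'"
            )
        scores = x / x_lowest
    return ActivityMatrix(
        scores=pd.DataFrame(scores, index=ec50.index, columns=ec50.columns),
        mode=mode,
        cap=cap,
    )


def render_activity_heatmap(matrix: ActivityMatrix, path) -> None:
    """Render the activity matrix as a green-to-red heatmap PNG/SVG.

    Low scores (high activity) are red, high scores (weak or no
    activity) green.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = matrix.scores
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(matrix.ligands), 1.0 + 0.5 * len(matrix.receptors))
    )
    im = ax.imshow(scores.to_numpy(), cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(len(matrix.ligands)), matrix.ligands, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.receptors)), matrix.receptors)
    fig.colorbar(im, ax=ax, label=f"activity score ({matrix.mode}, cap {matrix.cap:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
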