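"""Amino-acid distance matrices from trimmed multiple sequence alignments.

Receptor phylogenies here are distance-based: an aligned set of GPCR
sequences (typically trimmed to the TM1-TM7 region) is reduced to a
pairwise distance matrix under either the uncorrected proportion of
differing sites (p-distance) or its Poisson multiple-hit correction
``-ln(1 - p)``.  Gap handling follows the "complete deletion" convention:
every alignment column containing a gap in *any* sequence is discarded
before counting differences, so all pairs are scored over the same set of
columns.

Uncertainty on the distances is estimated by bootstrapping alignment
columns: columns are resampled with replacement, complete deletion is
re-applied per replicate, and the per-pair standard deviation across
replicates is reported as a standard error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix

GAP = "-"

_MODELS = ("p_distance", "poisson")


@dataclass
class Alignment:
    """An aligned set of equal-length amino-acid sequences.

    Parameters
    ----------
    labels : list of str
        Unique sequence names.
    sequences : list of str
        Aligned sequences; ``-`` marks gap columns.
    region : tuple of (int, int), optional
        Half-open, 0-based column range the alignment was trimmed to
        (e.g. the TM1-TM7 span).  Recorded for provenance; the stored
        sequences are already sliced.
    """

    labels: list[str]
    sequences: list[str]
    region: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in count")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate sequence labels: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n_sequences, n_columns) byte array."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(len(self.sequences), -1)

    def slice(self, region: tuple[int, int]) -> "Alignment":
        start, stop = region
        if not (0 <= start <= stop <= self.n_columns):
            raise ValueError(
                f"region {region} out of bounds for alignment of "
                f"length {self.n_columns}"
            )
        return Alignment(
            labels=list(self.labels),
            sequences=[s[start:stop] for s in self.sequences],
            region=(start, stop),
        )

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in zip(self.labels, self.sequences):
                fh.write(f">{label}\n{seq}\n")


def read_alignment(path, region: tuple[int, int] | None = None) -> Alignment:
    """Read an aligned FASTA file, optionally trimming to a column range.

    Parameters
    ----------
    path : str or path-like
        Aligned FASTA file.
    region : (start, stop), optional
        Half-open 0-based column range (e.g. the TM1-TM7 coordinates).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    aln = Alignment(
        labels=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
    )
    if region is not None:
        aln = aln.slice(region)
    return aln


def _ungapped_columns(arr: np.ndarray) -> np.ndarray:
    """Boolean mask of columns free of gaps in every sequence."""
    return ~(arr == GAP.encode()).any(axis=0)


def _pairwise_p(arr: np.ndarray) -> np.ndarray:
    """Pairwise proportion of differing sites over the given columns."""
    n, ncols = arr.shape
    if ncols == 0:
        raise ValueError("no columns retained after complete deletion of gaps")
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = np.count_nonzero(arr[i] != arr[j]) / ncols
        out[i, j] = out[j, i] = p
    return out


def _apply_model(p: np.ndarray, model: str) -> np.ndarray:
    if model == "p_distance":
        return p
    if model == "poisson":
        if np.any(p >= 1.0):
            raise ValueError(
                "Poisson correction undefined: some pair differs at every "
                "retained site (p = 1)"
            )
        return -np.log1p(-p)
    raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")


def pairwise_distance(
    alignment: Alignment,
    model: str = "p_distance",
    gap_handling: str = "complete_deletion",
) -> DistanceMatrix:
    """Pairwise distances between aligned sequences.

    Complete deletion drops every column containing a gap in any sequence,
    then ``p`` = mismatches / retained columns; the ``poisson`` model
    applies the multiple-hit correction ``-ln(1 - p)``.

    Returns
    -------
    skbio.DistanceMatrix
        Symmetric matrix keyed by the alignment labels.
    """
    if gap_handling != "complete_deletion":
        raise ValueError(f"unsupported gap handling {gap_handling!r}")
    arr = alignment.to_array()
    arr = arr[:, _ungapped_columns(arr)]
    p = _pairwise_p(arr)
    return DistanceMatrix(_apply_model(p, model), ids=alignment.labels)


@dataclass
class BootstrapDistances:
    """Point distances plus bootstrap standard errors."""

    point: DistanceMatrix
    se: DistanceMatrix
    n_replicates: int
    n_redrawn: int  # replicates redrawn because no column survived deletion


def bootstrap_distances(
    alignment: Alignment,
    n: int = 1000,
    seed: int = 0,
    model: str = "p_distance",
) -> BootstrapDistances:
    """Bootstrap alignment columns to attach standard errors to distances.

    Columns are resampled with replacement *before* complete deletion, so
    each replicate applies deletion to its own resample.  The reported
    ``se`` is the per-pair standard deviation across replicates; the point
    estimate is the ordinary (non-resampled) distance matrix.  Replicates
    in which every resampled column carries a gap (or that leave the
    Poisson correction undefined) are redrawn and counted.
    """
    if n < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    point = pairwise_distance(alignment, model=model)
    arr = alignment.to_array()
    ntax, ncols = arr.shape
    rng = np.random.default_rng(seed)
    reps = np.empty((n, ntax, ntax))
    redrawn = 0
    i = 0
    while i < n:
        cols = rng.integers(0, ncols, size=ncols)
        sub = arr[:, cols]
        sub = sub[:, _ungapped_columns(sub)]
        try:
            reps[i] = _apply_model(_pairwise_p(sub), model)
        except ValueError:
            redrawn += 1
            if redrawn > 100 * n:
                raise ValueError(
                    "bootstrap failed: could not draw replicates with "
                    "gap-free columns"
                )
            continue
        i += 1
    se = reps.std(axis=0, ddof=1)
    np.fill_diagonal(se, 0.0)
    se = (se + se.T) / 2  # exact symmetry against fp noise
    return BootstrapDistances(
        point=point,
        se=DistanceMatrix(se, ids=alignment.labels),
        n_replicates=n,
        n_redrawn=redrawn,
    )
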