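"""Ground-truth simulators for every stage of the pipeline.

Three generators, each seeded and deterministic:

* **Assay plates** — luminescence readings for receptor-ligand series
  following a known four-parameter logistic (4PL) truth, sampled over a
  10-fold dilution series (default 0.01 nM to 10 uM, the standard
  deorphanization design) with multiplicative log-normal noise of given
  coefficient of variation.  Non-responding pairs are flat curves
  (top = bottom).
* **Alignments** — amino-acid sequences evolved along a tree under the
  20-state equal-rates (Poisson) model: substitution events are placed
  by a Poisson process along each branch (lengths in expected
  substitutions/site) and each event jumps uniformly to one of the 19
  other residues.  Closed-form check: two sequences separated by total
  branch length b differ at a site with probability
  ``p = (19/20) (1 - exp(-(20/19) b))``.
* **Coevolution scenarios** — a joint panel of receptors with one
  authentic ligand each, built so that in the null case the functional
  (Euclidean activity-profile) distances are exactly proportional to the
  emitted ground-truth sequence distances; planted pleiotropic pairs
  break the proportionality by making one receptor additionally
  sensitive to its partner's authentic ligand (EC50 lowered by
  ``effect_size`` log10 units).  Sequences diverge along a tree fitted
  to the null functional structure, so estimated sequence distances
  track the truth up to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from zlib import crc32

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .dose_response import PLATE_COLUMNS, four_pl
from .trees import neighbor_joining, read_newick

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def default_concentrations(start_nM: float = 0.01, n_steps: int = 7) -> np.ndarray:
    """10-fold dilution series; defaults span 0.01 nM to 10 uM."""
    return start_nM * 10.0 ** np.arange(n_steps)


@dataclass
class FourPL:
    """True 4PL parameters for one (receptor, ligand) pair."""

    bottom: float
    top: float
    log10_ec50_nM: float
    hill: float = 1.0


@dataclass
class AssaySimSpec:
    """Design of a simulated assay plate.

    ``true_params`` must provide the 4PL truth for every
    (receptor, ligand) combination; simulate a non-responder by setting
    ``top == bottom``.  ``noise_cv`` is the coefficient of variation of
    multiplicative log-normal noise with unit mean, so expected readings
    equal the 4PL curve at any noise level.
    """

    receptors: list[str]
    ligands: list[str]
    true_params: dict[tuple[str, str], FourPL]
    concentrations: np.ndarray = field(default_factory=default_concentrations)
    replicates: int = 3
    noise_cv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or conc.size == 0 or np.any(conc <= 0):
            raise ValueError("concentrations: must be a nonempty positive 1-D series")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations: must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates: must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv: must be >= 0")
        if not self.receptors or not self.ligands:
            raise ValueError("receptors/ligands: must be nonempty")
        missing = [
            (r, l)
            for r in self.receptors
            for l in self.ligands
            if (r, l) not in self.true_params
        ]
        if missing:
            raise ValueError(f"true_params: missing entries for {missing}")


def simulate_dose_response(spec: AssaySimSpec) -> pd.DataFrame:
    """Simulate an assay plate: one reading per (receptor, ligand, conc, rep).

    The RNG is split deterministically per (receptor, ligand) series so
    any subset of the plate is reproducible on its own.
    """
    spec.validate()
    conc = np.asarray(spec.concentrations, dtype=float)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    rows = []
    for receptor in spec.receptors:
        for ligand in spec.ligands:
            p = spec.true_params[(receptor, ligand)]
            mean = four_pl(conc, p.bottom, p.top, p.log10_ec50_nM, p.hill)
            # label-keyed stream: a series is reproducible in any subset plate
            rng = np.random.default_rng(
                [spec.seed, crc32(receptor.encode()), crc32(ligand.encode())]
            )
            if sigma > 0:
                factors = np.exp(
                    rng.normal(-0.5 * sigma**2, sigma, size=(conc.size, spec.replicates))
                )
            else:
                factors = np.ones((conc.size, spec.replicates))
            for ci, c in enumerate(conc):
                for rep in range(spec.replicates):
                    rows.append(
                        (receptor, ligand, c, rep + 1, mean[ci] * factors[ci, rep])
                    )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


@dataclass
class EvolSimSpec:
    """Design of a simulated protein alignment.

    ``tree`` is a rooted tree (skbio TreeNode or Newick text) with branch
    lengths in expected substitutions per site; tips must be uniquely
    named.  Substitution model: 20-state equal rates.
    """

    tree: TreeNode | str
    seq_length: int
    seed: int = 0

    def resolved_tree(self) -> TreeNode:
        tree = self.tree
        if isinstance(tree, str):
            tree = read_newick(tree)
        return tree

    def validate(self) -> TreeNode:
        if self.seq_length < 1:
            raise ValueError("seq_length: must be >= 1")
        tree = self.resolved_tree()
        tips = [t.name for t in tree.tips()]
        if not tips:
            raise ValueError("tree: has no tips")
        if any(name is None for name in tips):
            raise ValueError("tree: all tips must be named")
        if len(set(tips)) != len(tips):
            raise ValueError("tree: tip names must be unique")
        for node in tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValueError("tree: branch lengths must be >= 0")
        return tree


def _evolve(seq: np.ndarray, branch_length: float, rng) -> np.ndarray:
    """Apply Poisson(branch_length) substitution events per site."""
    out = seq.copy()
    if branch_length <= 0:
        return out
    events = rng.poisson(branch_length, seq.size)
    for round_ in range(int(events.max()) if events.size else 0):
        mask = events > round_
        n = int(mask.sum())
        if n == 0:
            break
        jumps = rng.integers(1, 20, size=n)
        out[mask] = (out[mask] + jumps) % 20
    return out


def simulate_alignment(spec: EvolSimSpec):
    """Evolve sequences down the tree; returns a gap-free Alignment."""
    from .seqdist import Alignment

    tree = spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    sequences: dict[str, str] = {}

    def recurse(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve(seq, child.length or 0.0, rng)
            if child.is_tip():
                sequences[child.name] = "".join(AMINO_ACIDS[i] for i in child_seq)
            else:
                recurse(child, child_seq)

    root_seq = rng.integers(0, 20, size=spec.seq_length)
    if tree.is_tip():
        sequences[tree.name] = "".join(AMINO_ACIDS[i] for i in root_seq)
    else:
        recurse(tree, root_seq)
    labels = [t.name for t in tree.tips()] or [tree.name]
    return Alignment(labels=labels, sequences=[sequences[l] for l in labels])


@dataclass
class CoevolutionScenario:
    """A fully specified ligand-receptor coevolution test case."""

    alignment: object  # seqdist.Alignment
    assay_spec: AssaySimSpec
    authentic_map: dict[str, list[str]]
    tree: TreeNode
    true_activity: pd.DataFrame  # log10-EC50 activity scores, planted effects included
    true_functional: DistanceMatrix  # Euclidean distances of true_activity rows
    true_seq_rel: DistanceMatrix  # ground-truth relative sequence distances (max 1)
    planted_pairs: list[tuple[str, str]]
    effect_size: float


def simulate_coevolution_scenario(
    n_receptors: int,
    planted_pleiotropy_pairs: list[tuple[str, str]] | None = None,
    effect_size: float = 3.0,
    seed: int = 0,
    noise_cv: float = 0.05,
    seq_length: int = 600,
    replicates: int = 3,
    activity_spread: float = 3.0,
    max_tree_depth: float = 0.6,
) -> CoevolutionScenario:
    """Build a receptor panel with known coevolutionary structure.

    Each receptor ``R_i`` has one authentic ligand ``L_i`` with true EC50
    1 nM.  Receptors are placed at random positions on a latent
    specificity axis; the true activity score (log10 potency loss) of
    ligand ``L_j`` on receptor ``R_i`` is ``activity_spread`` times their
    positional separation, so functional distances grow with divergence
    and the ground-truth sequence distances (emitted as
    ``true_seq_rel``) are exactly proportional to the null functional
    distances.  For each planted pair ``(a, b)``, receptor ``b``'s EC50
    for ``a``'s authentic ligand is lowered by ``effect_size`` log10
    units (floored at the authentic potency) — the one-way retained
    sensitivity that constitutes positive pleiotropy.  Sequences evolve
    along a tree fitted to the null functional structure, scaled to
    ``max_tree_depth`` expected substitutions/site at the deepest split.
    """
    if n_receptors < 4:
        raise ValueError("n_receptors: must be >= 4")
    if effect_size <= 0:
        raise ValueError("effect_size: must be > 0")
    planted = [tuple(p) for p in (planted_pleiotropy_pairs or [])]
    width = len(str(n_receptors))
    receptors = [f"R{i + 1:0{width}d}" for i in range(n_receptors)]
    ligands = [f"L{i + 1:0{width}d}" for i in range(n_receptors)]
    index = {r: i for i, r in enumerate(receptors)}
    for a, b in planted:
        if a not in index or b not in index or a == b:
            raise ValueError(f"planted pair ({a!r}, {b!r}) is not a valid receptor pair")

    rng = np.random.default_rng([seed, 12021])
    # latent specificity positions: jittered even spacing guarantees the
    # panel spans the axis while keeping pair separations random
    jitter = rng.uniform(-0.4, 0.4, size=n_receptors) / max(n_receptors - 1, 1)
    positions = np.sort(np.linspace(0.0, 1.0, n_receptors) + jitter)
    sep = np.abs(positions[:, None] - positions[None, :])
    scores_null = activity_spread * sep  # authentic diagonal = 0
    scores = scores_null.copy()
    for a, b in planted:
        ia, ib = index[a], index[b]
        scores[ib, ia] = max(0.0, scores_null[ib, ia] - effect_size)

    func_null = squareform(pdist(scores_null, metric="euclidean"))
    true_seq_rel = DistanceMatrix(func_null / func_null.max(), ids=receptors)
    true_functional = DistanceMatrix(
        squareform(pdist(scores, metric="euclidean")), ids=receptors
    )

    tree = neighbor_joining(
        DistanceMatrix(func_null / func_null.max() * max_tree_depth, ids=receptors)
    )
    alignment = simulate_alignment(
        EvolSimSpec(tree=tree, seq_length=seq_length, seed=seed)
    )

    true_params = {
        (receptors[i], ligands[j]): FourPL(
            bottom=0.0, top=1.0, log10_ec50_nM=float(scores[i, j]), hill=1.0
        )
        for i in range(n_receptors)
        for j in range(n_receptors)
    }
    assay_spec = AssaySimSpec(
        receptors=receptors,
        ligands=ligands,
        true_params=true_params,
        replicates=replicates,
        noise_cv=noise_cv,
        seed=seed,
    )
    return CoevolutionScenario(
        alignment=alignment,
        assay_spec=assay_spec,
        authentic_map={r: [l] for r, l in zip(receptors, ligands)},
        tree=tree,
        true_activity=pd.DataFrame(scores, index=receptors, columns=ligands),
        true_functional=true_functional,
        true_seq_rel=true_seq_rel,
        planted_pairs=planted,
        effect_size=effect_size,
    )
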