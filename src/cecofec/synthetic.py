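"""Synthetic paired cecum/feces datasets with known ground truth.

The generator emulates the processed output of a paired 16S amplicon study
in which each of ~21 animals contributes one cecal and one fecal sample
under one of two feeding regimes.  For animal i, OTU k and origin o the
expected log abundance is

    eta_ik(o) = base_k + a_ik + delta_k * I(o = cecum) + gamma_k * I(restricted)

where base_k is a log-normal baseline (rank-abundance skew), a_ik is an
animal random effect shared by the animal's two samples, delta_k is the
planted origin effect (nonzero only for the flagged differential OTUs,
random sign so both origins harbour overrepresented OTUs), and gamma_k is
a feeding-regime effect restricted to a designated OTU subset.  A library
size is drawn uniformly from ``depth_range`` and allocated across OTUs by
a gamma-multinomial (Dirichlet-multinomial) scheme: per-OTU gamma
intensities with shape ``dispersion`` around exp(eta) are normalized and
fed to a multinomial draw, i.e. negative-binomial-style overdispersion
conditioned on the library size, so column totals land exactly in range.

Per-sample log-intensity noise has standard deviation
``sqrt(trigamma(dispersion))`` (see :func:`noise_sd`); effect sizes are
naturally expressed as multiples of it.

All draws consume a single seeded :class:`numpy.random.Generator` in a
fixed, documented order, so a seed pins the whole dataset bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import polygamma
from skbio import TreeNode

from cecofec.core_tables import OtuTable, SampleMetadata, TableError

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "generate_dataset",
    "generate_random_tree",
    "noise_sd",
]


def noise_sd(dispersion: float) -> float:
    """SD of per-sample log-intensity noise implied by the gamma shape.

    log Gamma(shape=r, scale=mu/r) has variance trigamma(r); this is the
    natural unit for expressing planted log-scale effect sizes.
    """
    return float(np.sqrt(polygamma(1, dispersion)))


def paired_noise_sd(dispersion: float) -> float:
    """SD of the within-pair (cecum - feces) log-intensity noise.

    Two independent per-sample draws contribute, so this is
    sqrt(2) * :func:`noise_sd`; a planted effect of 1.5 x this value is a
    paired standardized effect (Cohen's d_z) of 1.5.
    """
    return float(np.sqrt(2.0)) * noise_sd(dispersion)


@dataclass(frozen=True)
class SyntheticParams:
    """Generative parameters for a paired cecum/feces dataset.

    Defaults reproduce the emulated study's design scale: 21 animals
    (11 restricted, 10 ad libitum), 596 OTUs, per-sample depths uniform in
    16,415-68,080 reads, and ~30% of OTUs carrying an origin effect.
    """

    n_animals: int = 21
    n_otus: int = 596
    frac_differential: float = 0.30
    origin_effect_size: float = 0.5  # |delta_k|, natural-log scale
    animal_sd: float = 0.25  # SD of per-(animal, OTU) random effect
    regime_effect_size: float = 0.15  # gamma, applied to a 20% OTU subset
    depth_range: tuple[int, int] = (16415, 68080)
    dispersion: float = 10.0  # gamma shape; noise_sd(10) ~ 0.324
    base_log_sd: float = 2.0  # SD of log-normal baseline abundances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise TableError("n_animals must be >= 2")
        if self.n_otus < 2:
            raise TableError("n_otus must be >= 2")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise TableError("frac_differential must be in [0, 1]")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise TableError("depth_range must satisfy 1 <= min <= max")
        if min(self.animal_sd, self.base_log_sd) < 0 or self.dispersion <= 0:
            raise TableError("SDs must be >= 0 and dispersion > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset (for recovery tests)."""

    differential_otu_ids: frozenset[str]
    log_fold_effects: Mapping[str, float]  # delta_k, cecum minus feces, all OTUs
    animal_effects: Mapping[str, np.ndarray]  # animal_id -> per-OTU a_ik
    regime_affected_otu_ids: frozenset[str] = field(default_factory=frozenset)


def generate_random_tree(otu_ids, seed: int) -> TreeNode:
    """Random rooted binary tree over ``otu_ids`` with Exp(1) branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees; with n tips
    the result has n-1 internal nodes and a length-0 root.
    """
    otu_ids = [str(o) for o in otu_ids]
    if len(otu_ids) < 2:
        raise TableError("need at least 2 OTU ids for a tree")
    if len(set(otu_ids)) != len(otu_ids):
        raise TableError("duplicate OTU ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=o) for o in otu_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(1.0))
        right.length = float(rng.exponential(1.0))
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = None
    return root


def _synthetic_taxonomy(tree: TreeNode, otu_ids, rng: np.random.Generator,
                        n_phyla: int = 8) -> dict[str, str]:
    """Greengenes-style lineage strings assigned by clade.

    Tips are taken in tree (postorder) order, which is clade-contiguous,
    and sliced into phyla and genera.  Assignment depth mimics short-read
    resolution: every assigned OTU resolves to order, about half to family,
    about a fifth to genus, and a small fraction is entirely unassigned.
    """
    tip_order = [t.name for t in tree.tips()]
    n = len(tip_order)
    n_phyla = min(n_phyla, n)
    taxonomy: dict[str, str] = {}
    u_unassigned = rng.random(n)
    u_family = rng.random(n)
    u_genus = rng.random(n)
    for pos, otu in enumerate(tip_order):
        ph = pos * n_phyla // n + 1
        genus_block = pos * (3 * n_phyla) // n + 1
        if u_unassigned[pos] < 0.03:
            taxonomy[otu] = ""
            continue
        ranks = [
            "k__Bacteria",
            f"p__SynPhylum{ph}",
            f"c__SynClass{ph}",
            f"o__SynOrder{ph}",
            f"f__SynFamily{genus_block}" if u_family[pos] < 0.5 else "f__",
            f"g__SynGenus{genus_block}" if u_genus[pos] < 0.2 else "g__",
            "s__",
        ]
        taxonomy[otu] = "; ".join(ranks)
    return {o: taxonomy[o] for o in otu_ids}


def generate_dataset(params: SyntheticParams):
    """Generate (OtuTable, metadata, taxonomy, tree, SyntheticTruth).

    Draw order from the single seeded generator: baseline abundances,
    differential-OTU subset and signs, regime-affected subset, animal
    effects, tree seed, taxonomy depth draws, then per sample (animals in
    order, cecum before feces) the library size, gamma intensities and the
    multinomial allocation.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    otu_ids = tuple(f"OTU{k + 1:04d}" for k in range(p.n_otus))
    animal_ids = tuple(f"A{i + 1:03d}" for i in range(p.n_animals))

    base = rng.normal(0.0, p.base_log_sd, size=p.n_otus)

    n_diff = round(p.frac_differential * p.n_otus)
    diff_idx = np.sort(rng.choice(p.n_otus, size=n_diff, replace=False))
    delta = np.zeros(p.n_otus)
    if n_diff:
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        delta[diff_idx] = signs * p.origin_effect_size

    n_regime = round(0.2 * p.n_otus)
    regime_idx = np.sort(rng.choice(p.n_otus, size=n_regime, replace=False))
    gamma = np.zeros(p.n_otus)
    gamma[regime_idx] = p.regime_effect_size

    animal_eff = rng.normal(0.0, p.animal_sd, size=(p.n_animals, p.n_otus))

    tree_seed = int(rng.integers(2**31))
    tree = generate_random_tree(otu_ids, tree_seed)
    taxonomy = _synthetic_taxonomy(tree, otu_ids, rng)

    # regimes and size classes at the emulated study's frequencies
    n_restricted = int(round(p.n_animals * 11 / 21))
    regimes = ["restricted"] * n_restricted + ["ad_libitum"] * (p.n_animals - n_restricted)
    n_small_r = int(round(n_restricted * 4 / 11))
    n_small_v = int(round((p.n_animals - n_restricted) * 1 / 10))
    sizes = (
        ["small"] * n_small_r + ["big"] * (n_restricted - n_small_r)
        + ["small"] * n_small_v + ["big"] * (p.n_animals - n_restricted - n_small_v)
    )

    counts = np.zeros((2 * p.n_animals, p.n_otus), dtype=np.int64)
    sample_ids = []
    meta: dict[str, SampleMetadata] = {}
    row = 0
    for i, animal in enumerate(animal_ids):
        restricted = regimes[i] == "restricted"
        for origin in ("cecum", "feces"):
            sid = f"{animal}_{'C' if origin == 'cecum' else 'F'}"
            eta = base + animal_eff[i] + (delta if origin == "cecum" else 0.0)
            if restricted:
                eta = eta + gamma
            depth = int(rng.integers(p.depth_range[0], p.depth_range[1] + 1))
            intensity = rng.gamma(shape=p.dispersion, scale=np.exp(eta) / p.dispersion)
            if intensity.sum() == 0:  # pathological tiny-dispersion corner
                intensity = np.exp(eta)
            counts[row] = rng.multinomial(depth, intensity / intensity.sum())
            sample_ids.append(sid)
            meta[sid] = SampleMetadata(sid, animal, origin, regimes[i], sizes[i])
            row += 1

    table = OtuTable(counts, tuple(sample_ids), otu_ids)
    truth = SyntheticTruth(
        differential_otu_ids=frozenset(otu_ids[k] for k in diff_idx),
        log_fold_effects={otu_ids[k]: float(delta[k]) for k in range(p.n_otus)},
        animal_effects={animal_ids[i]: animal_eff[i].copy() for i in range(p.n_animals)},
        regime_affected_otu_ids=frozenset(otu_ids[k] for k in regime_idx),
    )
    return table, meta, taxonomy, tree, truth
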