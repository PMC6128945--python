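"""Structured-coalescent engine for three-population split-with-migration
histories.

The history is the fixed topology supported for the grasshopper system:
the southern lineage splits first (at T_DIV2, backward in time the deeper
event) and the north/central lineages split later (T_DIV1 <= T_DIV2).
Between the two splits the north-central ancestor can exchange migrants
with the southern deme (m_ANC); before T_DIV1 the contemporary demes can
exchange migrants (m_NC between north and central, m_CS between central
and south). Six model variants A..F switch these rates on or off.

Sizes are diploid effective sizes: a deme of size N coalesces k lineages
at rate k(k-1)/(4N) per generation. Migration rates are backward
per-lineage rates (the probability per generation that a lineage's parent
came from the other deme), symmetric within each connected pair. Time is
continuous with exponential waiting times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._kernels import accumulate_branch_sfs, simulate_sites, simulate_trees
from .genotypes import GenotypeMatrix
from .sfs import fold_joint

MODEL_IDS = ("A", "B", "C", "D", "E", "F")

#: migration rates active under each model variant
MODEL_MIGRATIONS: dict[str, tuple[str, ...]] = {
    "A": ("m_anc", "m_nc", "m_cs"),
    "B": ("m_anc", "m_nc"),
    "C": ("m_nc", "m_cs"),
    "D": ("m_anc",),
    "E": ("m_nc",),
    "F": (),
}

SIZE_PARAMS = ("theta_n", "theta_c", "theta_s", "theta_nc", "theta_anc")
TIME_PARAMS = ("t_div1", "t_div2")


@dataclass
class EpochModel:
    """Piecewise-constant structured model in kernel form.

    Arrays are indexed by epoch; `dest[e]` remaps lineage demes on entry
    to epoch e. Any deme count is allowed (the six-locality synthetic
    generator uses six demes nested in the three-group history).
    """

    epoch_ends: np.ndarray
    sizes: np.ndarray
    mig: np.ndarray
    dest: np.ndarray


@dataclass
class DemographicModel:
    """Parameters of one split-with-migration model variant.

    Sizes (`theta_*`) are diploid effective sizes; times are in
    generations with 0 < t_div1 <= t_div2; migration rates are
    per-generation backward probabilities in [0, 1). Rates not active
    under `model_id` must be zero.
    """

    model_id: str
    theta_n: float
    theta_c: float
    theta_s: float
    theta_nc: float
    theta_anc: float
    t_div1: float
    t_div2: float
    m_anc: float = 0.0
    m_nc: float = 0.0
    m_cs: float = 0.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        for name in SIZE_PARAMS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.t_div1 <= self.t_div2:
            raise ValueError("need 0 < t_div1 <= t_div2")
        active = MODEL_MIGRATIONS[self.model_id]
        for name in ("m_anc", "m_nc", "m_cs"):
            m = getattr(self, name)
            if not 0 <= m < 1:
                raise ValueError(f"{name} must be in [0, 1)")
            if m != 0 and name not in active:
                raise ValueError(
                    f"{name} is not active under model {self.model_id}"
                )

    def free_params(self) -> list[str]:
        """Free parameters when fitting (theta_s is always fixed)."""
        return [
            "theta_n",
            "theta_c",
            "theta_nc",
            "theta_anc",
            "t_div1",
            "t_div2",
            *MODEL_MIGRATIONS[self.model_id],
        ]

    def to_epochs(self) -> EpochModel:
        """Three-deme kernel arrays: demes (0=N, 1=C, 2=S).

        After T_DIV1 the north-central ancestor occupies deme 1 with size
        theta_nc; after T_DIV2 deme 1 holds the root with size theta_anc.
        """
        epoch_ends = np.array([self.t_div1, self.t_div2, np.inf])
        sizes = np.array(
            [
                [self.theta_n, self.theta_c, self.theta_s],
                [1.0, self.theta_nc, self.theta_s],
                [1.0, self.theta_anc, 1.0],
            ]
        )
        mig = np.zeros((3, 3, 3))
        mig[0, 0, 1] = mig[0, 1, 0] = self.m_nc
        mig[0, 1, 2] = mig[0, 2, 1] = self.m_cs
        mig[1, 1, 2] = mig[1, 2, 1] = self.m_anc
        dest = np.tile(np.arange(3, dtype=np.int64), (3, 1))
        dest[1] = [1, 1, 2]
        dest[2] = [1, 1, 1]
        return EpochModel(epoch_ends, sizes, mig, dest)

    # -- flat key=value serialization (CLI model files) --------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"model_id={self.model_id}\n")
            for name in (*SIZE_PARAMS, *TIME_PARAMS, "m_anc", "m_nc", "m_cs"):
                fh.write(f"{name}={getattr(self, name)!r}\n")

    @classmethod
    def from_file(cls, path) -> "DemographicModel":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        model_id = kv.pop("model_id")
        return cls(model_id=model_id, **{k: float(v) for k, v in kv.items()})


@dataclass
class SimulationConfig:
    """Sampling and simulation settings for the coalescent engine."""

    n_n: int = 14
    n_c: int = 16
    n_s: int = 8
    n_loci: int = 1000
    mu: float = 3.5e-9
    locus_length: int = 150
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        sizes = (self.n_n, self.n_c, self.n_s)
        if any(s < 0 for s in sizes) or sum(sizes) < 2:
            raise ValueError("need at least 2 haploid samples in total")

    @property
    def sample_sizes(self) -> tuple[int, int, int]:
        return (self.n_n, self.n_c, self.n_s)

    def sample_demes(self) -> np.ndarray:
        return np.array(
            [0] * self.n_n + [1] * self.n_c + [2] * self.n_s, dtype=np.int64
        )


def _kernel_seed(seed: int, *key: int) -> int:
    """Derive an independent 31-bit seed for a numba kernel call."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class Genealogy:
    """A single coalescent tree with per-branch sample configurations."""

    parents: np.ndarray
    times: np.ndarray
    sample_pops: np.ndarray  # group index (0, 1, 2) per leaf

    @property
    def n_samples(self) -> int:
        return (len(self.parents) + 1) // 2

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])

    def branches(self) -> Iterator[tuple[float, tuple[int, int, int]]]:
        """Yield (branch length, per-group descendant counts) per branch."""
        n_nodes = len(self.parents)
        cfg = np.zeros((n_nodes, 3), dtype=int)
        for i in range(self.n_samples):
            cfg[i, self.sample_pops[i]] = 1
        out = []
        for v in range(n_nodes - 1):
            p = self.parents[v]
            out.append((float(self.times[p] - self.times[v]), tuple(cfg[v])))
            cfg[p] += cfg[v]
        return iter(out)


def simulate_genealogy(
    model: DemographicModel | EpochModel,
    config: SimulationConfig,
    seed: int | None = None,
) -> Genealogy:
    """Simulate one genealogy under the structured coalescent."""
    ep = model.to_epochs() if isinstance(model, DemographicModel) else model
    demes = config.sample_demes()
    s = config.seed if seed is None else seed
    parents, times = simulate_trees(
        1, demes, ep.epoch_ends, ep.sizes, ep.mig, ep.dest, _kernel_seed(s, 0)
    )
    if not np.isfinite(times[0, -1]):
        raise FloatingPointError("genealogy time overflow")
    return Genealogy(parents[0], times[0], demes)


def tmrca_sample(
    model: DemographicModel | EpochModel,
    config: SimulationConfig,
    n_sims: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """TMRCA draws (generations) over replicate genealogies."""
    ep = model.to_epochs() if isinstance(model, DemographicModel) else model
    n = config.n_sims if n_sims is None else n_sims
    s = config.seed if seed is None else seed
    _, times = simulate_trees(
        n,
        config.sample_demes(),
        ep.epoch_ends,
        ep.sizes,
        ep.mig,
        ep.dest,
        _kernel_seed(s, 1),
    )
    return times[:, -1]


def expected_sfs(
    model: DemographicModel | EpochModel,
    config: SimulationConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo expected folded joint SFS conditioned on polymorphism.

    Each branch of each simulated genealogy contributes mass equal to its
    length to its descendant configuration (one-mutation infinite-sites
    weighting); the accumulation is folded, monomorphic corners removed,
    and the result normalized to a probability array.
    """
    if config.n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ep = model.to_epochs() if isinstance(model, DemographicModel) else model
    demes = config.sample_demes()
    s = config.seed if seed is None else seed
    parents, times = simulate_trees(
        config.n_sims,
        demes,
        ep.epoch_ends,
        ep.sizes,
        ep.mig,
        ep.dest,
        _kernel_seed(s, 2),
    )
    acc = accumulate_branch_sfs(
        parents, times, demes, config.n_n, config.n_c, config.n_s
    )
    folded = fold_joint(acc, mask_monomorphic=True)
    total = folded.sum()
    if total <= 0:
        raise ValueError("expected SFS accumulated zero mass")
    return folded / total


def simulate_genotypes_from_epochs(
    epochs: EpochModel,
    sample_demes: np.ndarray,
    individuals: list[str],
    populations: dict[str, str],
    n_loci: int,
    mu: float,
    locus_length: int,
    missing_rate: float,
    seed: int,
) -> GenotypeMatrix:
    """Simulate diploid biallelic SNP genotypes under any epoch model.

    One genealogy per locus; mutations are Poisson on total branch length
    at rate mu * locus_length; consecutive haploids pair into diploids in
    the order of `individuals` (two haploids each). Missing calls are
    injected uniformly at `missing_rate`.
    """
    import warnings

    n_hap = len(sample_demes)
    if n_hap != 2 * len(individuals):
        raise ValueError("sample_demes must hold two haploids per individual")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    parents, times = simulate_trees(
        n_loci,
        np.asarray(sample_demes, dtype=np.int64),
        epochs.epoch_ends,
        epochs.sizes,
        epochs.mig,
        epochs.dest,
        _kernel_seed(seed, 3),
    )
    derived, site_tree = simulate_sites(
        parents, times, mu * locus_length, _kernel_seed(seed, 4)
    )
    if derived.shape[0] == 0:
        warnings.warn("no polymorphic sites simulated", UserWarning, stacklevel=2)
    calls = (derived[:, 0::2] + derived[:, 1::2]).T.astype(np.int8)
    # within-locus positions: 1-based running index per tree
    pos = np.ones(len(site_tree), dtype=int)
    for i in range(1, len(site_tree)):
        if site_tree[i] == site_tree[i - 1]:
            pos[i] = pos[i - 1] + 1
    import pandas as pd

    loci = pd.DataFrame(
        {
            "locus_id": [f"locus_{t}" for t in site_tree],
            "pos": pos,
            "ref": "A",
            "alt": "T",
        }
    )
    if missing_rate > 0:
        rng = np.random.default_rng(_kernel_seed(seed, 5))
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, np.int8(-1), calls)
    return GenotypeMatrix(list(individuals), dict(populations), loci, calls)


def simulate_genotype_data(
    model: DemographicModel,
    config: SimulationConfig,
    diploid_sizes: tuple[int, int, int] = (7, 8, 4),
    missing_rate: float = 0.0,
    seed: int | None = None,
    pop_names: tuple[str, str, str] = ("north", "central", "south"),
) -> GenotypeMatrix:
    """Simulate a three-population genotype matrix under `model`."""
    s = config.seed if seed is None else seed
    individuals = []
    populations = {}
    demes = []
    for d, (pop, size) in enumerate(zip(pop_names, diploid_sizes)):
        for i in range(size):
            name = f"{pop}_{i}"
            individuals.append(name)
            populations[name] = pop
            demes += [d, d]
    return simulate_genotypes_from_epochs(
        model.to_epochs(),
        np.array(demes, dtype=np.int64),
        individuals,
        populations,
        config.n_loci,
        config.mu,
        config.locus_length,
        missing_rate,
        s,
    )
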