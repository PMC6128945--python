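"""Folded three-population joint site-frequency spectrum construction.

The joint SFS is indexed by alternate-allele counts in the (north,
central, south) groups and folded on the *global* minor allele: any
configuration whose total alternate count exceeds half the pooled haploid
sample size is complemented on all three axes, and exact-half ties are
split 50/50 between the two complementary cells. Monomorphic corners are
masked, matching SFS-based inference conditioned on polymorphism.

Missing data are removed by projecting each site's allele-count
distribution down to fixed haploid sample sizes by hypergeometric
expectation (the expected-SFS projection); a seeded random-subsampling
mode gives integer counts instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .genotypes import MISSING, GenotypeMatrix

_HEADER = "# basinflow folded joint SFS"


def fold_joint(acc: np.ndarray, mask_monomorphic: bool = True) -> np.ndarray:
    """Fold a joint allele-count accumulation array on the global minor allele.

    Cells with total count > half the pooled sample size receive zero and
    their mass moves to the complementary cell; exact-half ties are split
    equally. Idempotent.
    """
    acc = np.asarray(acc, dtype=float)
    n_tot = sum(d - 1 for d in acc.shape)
    grids = np.indices(acc.shape)
    total = sum(grids)
    rev = acc[tuple(slice(None, None, -1) for _ in acc.shape)]
    folded = np.where(
        2 * total < n_tot,
        acc + rev,
        np.where(2 * total == n_tot, (acc + rev) / 2.0, 0.0),
    )
    if mask_monomorphic:
        folded[(0,) * folded.ndim] = 0.0
        folded[(-1,) * folded.ndim] = 0.0
    return folded


@dataclass
class FoldedJointSFS:
    """Folded joint SFS over three population groups.

    `sample_sizes` are haploid counts (n_N, n_C, n_S); `counts` has shape
    (n_N+1, n_C+1, n_S+1) and may be real-valued when built by projection.
    """

    sample_sizes: tuple[int, int, int]
    counts: np.ndarray = field(repr=False)
    monomorphic_masked: bool = True
    pop_names: tuple[str, str, str] = ("north", "central", "south")

    def __post_init__(self):
        self.sample_sizes = tuple(int(s) for s in self.sample_sizes)
        self.counts = np.asarray(self.counts, dtype=float)
        expected = tuple(s + 1 for s in self.sample_sizes)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match sample sizes "
                f"{self.sample_sizes} (expected {expected})"
            )
        if (self.counts < -1e-12).any():
            raise ValueError("negative SFS counts")
        n_tot = sum(self.sample_sizes)
        total = sum(np.indices(self.counts.shape))
        if (self.counts[2 * total > n_tot] > 1e-9).any():
            raise ValueError("counts present above the folding boundary")
        if self.monomorphic_masked:
            if abs(self.counts[0, 0, 0]) > 1e-9 or abs(self.counts[-1, -1, -1]) > 1e-9:
                raise ValueError("monomorphic corner cells must be zero when masked")

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())

    def marginal(self, axis: int) -> np.ndarray:
        """1-D folded SFS of one group, marginalizing the other two."""
        axes = tuple(i for i in range(3) if i != axis)
        return fold_joint(
            self.counts.sum(axis=axes).reshape(-1), self.monomorphic_masked
        )

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_HEADER + "\n")
            fh.write(" ".join(str(s) for s in self.sample_sizes) + "\n")
            fh.write(" ".join(repr(float(v)) for v in self.counts.ravel()) + "\n")

    @classmethod
    def read(cls, path) -> "FoldedJointSFS":
        with open(path) as fh:
            lines = [l.strip() for l in fh if l.strip()]
        body_start = 1 if lines[0].startswith("#") else 0
        sizes = tuple(int(x) for x in lines[body_start].split())
        if len(sizes) != 3:
            raise ValueError(f"expected 3 sample sizes in header, got {sizes}")
        flat = np.array(
            [float(x) for line in lines[body_start + 1:] for x in line.split()]
        )
        n_expected = int(np.prod([s + 1 for s in sizes]))
        if flat.size != n_expected:
            raise ValueError(
                f"body has {flat.size} values, header implies {n_expected}"
            )
        return cls(sizes, flat.reshape(tuple(s + 1 for s in sizes)))


def thin_one_snp_per_locus(
    G: GenotypeMatrix, rule: str = "first", seed: int | None = None
) -> GenotypeMatrix:
    """Retain a single SNP per locus_id to avoid linkage disequilibrium.

    rule='first' keeps the lowest within-locus position; rule='random'
    draws one SNP per locus with a seeded generator.
    """
    if rule not in ("first", "random"):
        raise ValueError(f"rule must be 'first' or 'random', got {rule!r}")
    df = G.loci.reset_index()  # 'index' column = original column order
    if rule == "first":
        keep = df.sort_values(["locus_id", "pos"], kind="stable").groupby(
            "locus_id", sort=False
        )["index"].first()
    else:
        rng = np.random.default_rng(seed)
        keep = df.groupby("locus_id", sort=False)["index"].apply(
            lambda s: s.iloc[rng.integers(len(s))]
        )
    idx = np.sort(keep.to_numpy())
    return G.subset_loci(idx)


@dataclass
class ProjectedSites:
    """Per-site allele-count mass vectors after downsampling, per group."""

    group_names: tuple[str, str, str]
    haploid_sizes: tuple[int, int, int]
    vectors: list[np.ndarray]  # 3 arrays, each (n_sites, haploid_size+1)
    n_dropped: int

    @property
    def n_sites(self) -> int:
        return self.vectors[0].shape[0]


def downsample_projection(
    G: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    targets: Mapping[str, int],
    mode: str = "project",
    seed: int | None = None,
) -> ProjectedSites:
    """Project each site down to fixed per-group sample sizes.

    `groups` maps group name -> population labels; `targets` gives the
    diploid count per group (haploid size is twice that). Sites where any
    group has fewer called haploids than its target are dropped. In
    'project' mode the alternate-allele count distribution is the
    hypergeometric expectation over draws of the target haploids from the
    called ones (real-valued mass); 'subsample' draws one hypergeometric
    sample per site per group (integer counts).
    """
    if mode not in ("project", "subsample"):
        raise ValueError(f"mode must be 'project' or 'subsample', got {mode!r}")
    names = tuple(groups)
    if len(names) != 3:
        raise ValueError(f"exactly three groups required, got {len(names)}")
    for g in names:
        if g not in targets:
            raise ValueError(f"no target size for group {g!r}")
        if targets[g] <= 0:
            raise ValueError(f"target for group {g!r} must be positive")
    pop_idx = G.pop_indices()
    rng = np.random.default_rng(seed)

    n_hap = []
    alt = []
    for g in names:
        rows = np.concatenate([pop_idx[p] for p in groups[g]])
        sub = G.calls[rows]
        called = sub != MISSING
        n_hap.append(2 * called.sum(axis=0))
        alt.append(np.where(called, sub, 0).sum(axis=0))

    keep = np.ones(G.n_loci, dtype=bool)
    for g, n in zip(names, n_hap):
        keep &= n >= 2 * targets[g]
    n_dropped = int((~keep).sum())

    vectors = []
    sizes = []
    for g, n, a in zip(names, n_hap, alt):
        m = 2 * targets[g]
        sizes.append(m)
        nk = n[keep].astype(int)
        ak = a[keep].astype(int)
        j = np.arange(m + 1)
        if mode == "project":
            # P(j alt in m draws | a alt among n called) per site
            vec = hypergeom.pmf(
                j[None, :], nk[:, None], ak[:, None], m
            )
        else:
            draw = rng.hypergeometric(ak, nk - ak, m)
            vec = np.zeros((len(nk), m + 1))
            vec[np.arange(len(nk)), draw] = 1.0
        vectors.append(vec)
    return ProjectedSites(names, tuple(sizes), vectors, n_dropped)


def build_folded_sfs(proj: ProjectedSites) -> FoldedJointSFS:
    """Accumulate projected site masses into the folded joint SFS."""
    v0, v1, v2 = proj.vectors
    acc = np.einsum("si,sj,sk->ijk", v0, v1, v2)
    counts = fold_joint(acc, mask_monomorphic=True)
    return FoldedJointSFS(
        sample_sizes=proj.haploid_sizes,
        counts=counts,
        monomorphic_masked=True,
        pop_names=proj.group_names,
    )
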