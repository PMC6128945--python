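"""Synthetic study inputs: genotypes, landscapes and matrix sets.

Emulates the study design the pipeline targets: six localities sampled
5-6 diploids each, nested in three genetic groups (two northern, three
central, one southern) that occupy three river basins on a small grid.
Genotypes come from the structured coalescent with a six-deme refinement
of the three-group split-with-migration history — high within-group
migration reconciles six sampled localities with a three-group model, so
within-group differentiation stays low (F_ST near 0.06) while
between-lineage differentiation is strong (up to roughly 0.2-0.3).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import EpochModel, simulate_genotypes_from_epochs
from .genotypes import GenotypeMatrix
from .popgen import PairMatrix
from .raster import Raster

POPS = ("TAJU", "BELI", "PHUE", "SALI", "BONI", "ORCE")
GROUPS: dict[str, tuple[str, ...]] = {
    "north": ("TAJU", "BELI"),
    "central": ("PHUE", "SALI", "BONI"),
    "south": ("ORCE",),
}
#: locality cells (row, col) on the default 48x48 grid, one per basin group
_POP_CELLS = {
    "TAJU": (6, 10),
    "BELI": (8, 20),
    "PHUE": (22, 12),
    "SALI": (23, 22),
    "BONI": (26, 33),
    "ORCE": (42, 30),
}


@dataclass
class SyntheticStudySpec:
    """Generating conditions for the synthetic study.

    Demography defaults to the split-with-migration shape with ancestral
    and north-central gene flow at the scale inferred for the grasshopper
    system (sizes near 1e5, deep split 1.5e5 generations, shallow split
    2e4, migration 1e-5 scale). theta_s matches Ne = pi / 4mu at
    pi = 0.0011, mu = 3.5e-9.
    """

    theta_n: float = 1.66e5
    theta_c: float = 1.19e5
    theta_s: float = 7.857e4
    theta_nc: float = 1.51e5
    theta_anc: float = 9.5e4
    t_div1: float = 2.0e4
    t_div2: float = 1.5e5
    m_anc: float = 1.45e-5
    m_nc: float = 3.3e-5
    m_within: float = 2.5e-5
    n_loci: int = 10_167
    diploids: tuple[int, ...] = (5, 6, 6, 6, 6, 6)
    missing_rate: float = 0.05
    mu: float = 3.5e-9
    locus_length: int = 150
    grid_shape: tuple[int, int] = (48, 48)
    seed: int = 0

    def __post_init__(self):
        if len(self.diploids) != len(POPS):
            raise ValueError(f"need {len(POPS)} per-population sample sizes")
        if any(d <= 0 for d in self.diploids):
            raise ValueError("sample sizes must be positive")
        if min(self.grid_shape) < 40:
            raise ValueError("grid must be at least 40x40")


def _six_deme_epochs(spec: SyntheticStudySpec) -> EpochModel:
    """Six contemporary demes nested in the three-group history.

    Demes 0-1 (north) and 2-4 (central) exchange within-group migrants at
    m_within; between-group flow splits m_nc evenly over the other
    group's demes. At t_div1 demes 0-4 merge into the north-central
    ancestor; at t_div2 everything merges into the root.
    """
    n_demes = 6
    group_of = [0, 0, 1, 1, 1, 2]
    sizes0 = [
        spec.theta_n,
        spec.theta_n,
        spec.theta_c,
        spec.theta_c,
        spec.theta_c,
        spec.theta_s,
    ]
    mig0 = np.zeros((n_demes, n_demes))
    for a in range(n_demes):
        for b in range(n_demes):
            if a == b:
                continue
            ga, gb = group_of[a], group_of[b]
            n_gb = group_of.count(gb)
            if ga == gb:
                mig0[a, b] = spec.m_within / (n_gb - 1)
            elif {ga, gb} == {0, 1}:
                mig0[a, b] = spec.m_nc / n_gb
    epoch_ends = np.array([spec.t_div1, spec.t_div2, np.inf])
    sizes = np.ones((3, n_demes))
    sizes[0] = sizes0
    sizes[1, 2] = spec.theta_nc
    sizes[1, 5] = spec.theta_s
    sizes[2, 2] = spec.theta_anc
    mig = np.zeros((3, n_demes, n_demes))
    mig[0] = mig0
    mig[1, 2, 5] = mig[1, 5, 2] = spec.m_anc
    dest = np.tile(np.arange(n_demes, dtype=np.int64), (3, 1))
    dest[1] = [2, 2, 2, 2, 2, 5]
    dest[2] = [2, 2, 2, 2, 2, 2]
    return EpochModel(epoch_ends, sizes, mig, dest)


def focal_coordinates(spec: SyntheticStudySpec) -> dict[str, tuple[float, float]]:
    """Map-unit (x, y) cell centers of the six localities."""
    n_rows = spec.grid_shape[0]
    return {
        pop: (c + 0.5, (n_rows - 1 - r) + 0.5) for pop, (r, c) in _POP_CELLS.items()
    }


def make_genotypes(spec: SyntheticStudySpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the SNP matrix and its popmap under the six-deme history."""
    individuals: list[str] = []
    populations: dict[str, str] = {}
    demes: list[int] = []
    for d, (pop, n_dip) in enumerate(zip(POPS, spec.diploids)):
        for i in range(n_dip):
            name = f"{pop}_{i:02d}"
            individuals.append(name)
            populations[name] = pop
            demes += [d, d]
    G = simulate_genotypes_from_epochs(
        _six_deme_epochs(spec),
        np.array(demes, dtype=np.int64),
        individuals,
        populations,
        spec.n_loci,
        spec.mu,
        spec.locus_length,
        spec.missing_rate,
        spec.seed,
    )
    xy = focal_coordinates(spec)
    popmap = pd.DataFrame(
        {
            "individual": individuals,
            "population": [populations[i] for i in individuals],
            "latitude": [xy[populations[i]][1] for i in individuals],
            "longitude": [xy[populations[i]][0] for i in individuals],
        }
    )
    return G, popmap


#: habitat category codes
HABITAT_SUITABLE = 1  # natural grassland / sclerophyllous-type habitat
HABITAT_NATURAL_OTHER = 2
HABITAT_NONNATURAL = 3
LITHO_SUITABLE = 1  # evaporites / limestones / conglomerates analogue
LITHO_OTHER = 2


def _smooth_noise(shape, rng, scale=6):
    """Low-frequency random field in [0, 1] (bilinear-upsampled noise)."""
    coarse = rng.random((shape[0] // scale + 2, shape[1] // scale + 2))
    rows = np.linspace(0, coarse.shape[0] - 1.001, shape[0])
    cols = np.linspace(0, coarse.shape[1] - 1.001, shape[1])
    r0 = rows.astype(int)
    c0 = cols.astype(int)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    z = (
        coarse[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
        + coarse[np.ix_(r0 + 1, c0)] * fr * (1 - fc)
        + coarse[np.ix_(r0, c0 + 1)] * (1 - fr) * fc
        + coarse[np.ix_(r0 + 1, c0 + 1)] * fr * fc
    )
    return (z - z.min()) / (z.max() - z.min() + 1e-12)


def make_landscape(spec: SyntheticStudySpec) -> dict:
    """Toy three-basin landscape rasters plus focal coordinates.

    Returns basin, habitat, lithology and elevation rasters. Basin divides
    separate the three groups; habitat is a mosaic with suitable patches
    guaranteed at the localities; suitable lithology is widespread; the
    elevation field is predominantly flat with gentle rises at divides.
    """
    n_rows, n_cols = spec.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 7]))
    rr = np.arange(n_rows)[:, None] * np.ones((1, n_cols))
    cc = np.ones((n_rows, 1)) * np.arange(n_cols)[None, :]

    # two wavy divides split the grid into north / central / south basins
    div1 = 0.33 * n_rows + 2.0 * np.sin(2 * np.pi * cc[0] / n_cols * 1.7)
    div2 = 0.70 * n_rows + 2.0 * np.cos(2 * np.pi * cc[0] / n_cols * 1.3)
    basin = np.ones((n_rows, n_cols))
    basin[rr >= div1[None, :]] = 2
    basin[rr >= div2[None, :]] = 3

    habitat_field = _smooth_noise((n_rows, n_cols), rng)
    habitat = np.full((n_rows, n_cols), HABITAT_NATURAL_OTHER, dtype=float)
    habitat[habitat_field < 0.35] = HABITAT_SUITABLE
    habitat[habitat_field > 0.75] = HABITAT_NONNATURAL

    litho_field = _smooth_noise((n_rows, n_cols), rng)
    lithology = np.where(litho_field < 0.7, LITHO_SUITABLE, LITHO_OTHER).astype(float)

    ridge1 = 25.0 * np.exp(-((rr - div1[None, :]) ** 2) / (2 * 2.5**2))
    ridge2 = 25.0 * np.exp(-((rr - div2[None, :]) ** 2) / (2 * 2.5**2))
    elevation = (
        600.0
        + 15.0 * _smooth_noise((n_rows, n_cols), rng, scale=10)
        + ridge1
        + ridge2
    )

    for r, c in _POP_CELLS.values():
        habitat[r - 1 : r + 2, c - 1 : c + 2] = HABITAT_SUITABLE
        lithology[r - 1 : r + 2, c - 1 : c + 2] = LITHO_SUITABLE

    return {
        "basin": Raster(basin),
        "habitat": Raster(habitat),
        "lithology": Raster(lithology),
        "elevation": Raster(elevation),
        "focal_xy": focal_coordinates(spec),
    }


def make_matrix_set(
    n_pops: int,
    beta_true: tuple[float, ...],
    noise_sd: float,
    seed: int,
) -> tuple[PairMatrix, list[PairMatrix], np.ndarray]:
    """Response and predictor distance matrices with known coefficients.

    Each predictor is the Euclidean distance matrix of a random planar
    point configuration; the response composes the standardized unfolded
    predictors with `beta_true` plus symmetric Gaussian noise. Returns
    (Y, X list, beta_true).
    """
    if n_pops < 5:
        raise ValueError("need at least 5 populations")
    rng = np.random.default_rng(seed)
    labels = [f"pop{i}" for i in range(n_pops)]
    tril = np.tril_indices(n_pops, k=-1)
    Xs = []
    cols = []
    for _ in beta_true:
        pts = rng.random((n_pops, 2)) * 10.0
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        Xs.append(PairMatrix(labels, d))
        v = d[tril]
        cols.append((v - v.mean()) / v.std())
    yv = sum(b * c for b, c in zip(beta_true, cols))
    yv = yv + noise_sd * rng.standard_normal(len(cols[0]))
    ym = np.zeros((n_pops, n_pops))
    ym[tril] = yv
    Y = PairMatrix(labels, ym + ym.T)
    return Y, Xs, np.asarray(beta_true, dtype=float)
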