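"""Diploid SNP genotype container and locus filtering.

Genotypes are stored as alternate-allele dosages (0, 1, 2) with -1 for
missing calls, one row per individual and one column per SNP. Loci carry a
``locus_id`` (the RAD locus / assembly contig) and a within-locus position,
so multiple SNPs from one locus can be thinned later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


@dataclass(eq=False)
class GenotypeMatrix:
    """SNP genotypes for a set of individuals with a population map.

    Parameters
    ----------
    individuals : list of str
        Sample identifiers, one per row of `calls`.
    populations : dict
        Mapping individual id -> population label; every individual must
        be present.
    loci : pandas.DataFrame
        One row per SNP with columns ``locus_id``, ``pos``, ``ref``, ``alt``.
    calls : ndarray of int8, shape (n_individuals, n_loci)
        Alternate-allele dosage per call; -1 marks a missing genotype.
    """

    individuals: list[str]
    populations: dict[str, str]
    loci: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        missing_pop = [i for i in self.individuals if i not in self.populations]
        if missing_pop:
            raise ValueError(f"individuals without a population label: {missing_pop}")
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"malformed genotype codes: {sorted(bad)}")
        ids = list(zip(self.loci["locus_id"], self.loci["pos"]))
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate (locus_id, pos) entries in loci table")

    # -- basic shape -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each population's individuals."""
        out: dict[str, list[int]] = {p: [] for p in self.pop_labels}
        for i, ind in enumerate(self.individuals):
            out[self.populations[ind]].append(i)
        return {p: np.asarray(v, dtype=np.intp) for p, v in out.items()}

    def subset_loci(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            populations=dict(self.populations),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    # -- I/O ---------------------------------------------------------------

    def write_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT-only genotype fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=basinflow\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for locus_id in pd.unique(self.loci["locus_id"]):
                fh.write(f"##contig=<ID={locus_id}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.individuals)
                + "\n"
            )
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j, row in enumerate(self.loci.itertuples(index=False)):
                fields = [
                    str(row.locus_id),
                    str(int(row.pos)),
                    f"{row.locus_id}_{int(row.pos)}",
                    str(row.ref),
                    str(row.alt),
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                fields += [gt_str[int(c)] for c in self.calls[:, j]]
                fh.write("\t".join(fields) + "\n")


def read_popmap(path) -> pd.DataFrame:
    """Read a 4-column population map (individual, population, lat, lon)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["individual", "population", "latitude", "longitude"],
        dtype={"individual": str, "population": str},
    )
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].tolist()
        raise ValueError(f"duplicate individuals in popmap: {dup}")
    return df


def write_popmap(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_vcf(path, popmap: pd.DataFrame | str) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF, with populations from a popmap.

    Multi-allelic or non-SNP records are skipped. The VCF CHROM field is
    taken as the locus id and POS as the within-locus position.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, pd.DataFrame):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    known = set(popmap["individual"])
    unknown = [s for s in samples if s not in known]
    if unknown:
        raise ValueError(f"VCF samples missing from popmap: {unknown}")
    pops = dict(zip(popmap["individual"], popmap["population"]))

    rows = []
    calls_cols = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            col[i] = a + b if (a >= 0 and b >= 0) else MISSING
        calls_cols.append(col)
    loci = pd.DataFrame(rows, columns=["locus_id", "pos", "ref", "alt"])
    calls = (
        np.column_stack(calls_cols)
        if calls_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, pops, loci, calls)


def filter_loci(
    G: GenotypeMatrix, min_pops: int, min_ind_frac: float
) -> GenotypeMatrix:
    """Keep loci genotyped in at least `min_pops` populations.

    A population counts toward a locus only when at least `min_ind_frac`
    of its individuals have a non-missing call there (the p / r filters of
    RAD-locus pipelines). The individual set is unchanged.
    """
    n_pops = len(G.pop_labels)
    if not 1 <= min_pops <= n_pops:
        raise ValueError(f"min_pops must be in [1, {n_pops}], got {min_pops}")
    if not 0 < min_ind_frac <= 1:
        raise ValueError(f"min_ind_frac must be in (0, 1], got {min_ind_frac}")
    called = G.calls != MISSING
    qualifying = np.zeros(G.n_loci, dtype=np.int64)
    for idx in G.pop_indices().values():
        frac = called[idx].mean(axis=0)
        qualifying += frac >= min_ind_frac
    keep = qualifying >= min_pops
    if not keep.any():
        warnings.warn(
            f"filter_loci(min_pops={min_pops}, min_ind_frac={min_ind_frac}) "
            "removed every locus",
            UserWarning,
            stacklevel=2,
        )
    return G.subset_loci(keep)
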