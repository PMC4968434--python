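"""Core in-memory containers for the scan pipeline.

Everything downstream operates on two substrates: a phased site-by-chromosome
binary :class:`HaplotypeMatrix` and its diploid collapse, the
:class:`GenotypeMatrix` of allele dosages.  Coordinates are 0-based half-open
everywhere inside the package; conversion to/from 1-based happens exactly at
the VCF boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MISSING_DOSAGE = -1

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"Region {self.name!r}: start {self.start} >= end {self.end}")
        if not self.name:
            raise ValueError("Region name must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP.  ``ancestral_allele`` is None when unknown."""

    chrom: str
    pos: int  # 0-based
    id: str
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"site {self.id}: ref == alt ({self.ref_allele})")
        if self.ancestral_allele is not None and self.ancestral_allele not in (
            self.ref_allele,
            self.alt_allele,
        ):
            raise ValueError(
                f"site {self.id}: ancestral allele {self.ancestral_allele!r} "
                f"matches neither ref nor alt"
            )


@dataclass
class PopulationPanel:
    """sample_id -> (population, cluster) assignment.

    Clusters partition populations: each population label maps to exactly one
    cluster label.
    """

    population: dict[str, str]
    cluster: dict[str, str]

    def __post_init__(self):
        if set(self.population) != set(self.cluster):
            raise ValueError("population and cluster maps must cover the same samples")
        pop_to_cluster: dict[str, str] = {}
        for s, pop in self.population.items():
            cl = self.cluster[s]
            if pop_to_cluster.setdefault(pop, cl) != cl:
                raise ValueError(f"population {pop!r} assigned to multiple clusters")

    @property
    def samples(self) -> list[str]:
        return list(self.population)

    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cluster.values():
            seen.setdefault(c)
        return list(seen)

    def samples_in_cluster(self, cluster: str) -> list[str]:
        return [s for s, c in self.cluster.items() if c == cluster]

    @classmethod
    def from_tsv(cls, path) -> "PopulationPanel":
        pop, clu = {}, {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["sample_id", "population", "cluster"]:
                raise ValueError(f"panel header must be sample_id/population/cluster, got {header}")
            for line in fh:
                if not line.strip():
                    continue
                s, p, c = line.rstrip("\n").split("\t")[:3]
                if s in pop:
                    raise ValueError(f"duplicate sample {s} in panel")
                pop[s], clu[s] = p, c
        return cls(pop, clu)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\tcluster\n")
            for s in self.population:
                fh.write(f"{s}\t{self.population[s]}\t{self.cluster[s]}\n")


@dataclass
class HaplotypeMatrix:
    """Phased binary sites x chromosomes matrix.

    ``data[i, j]`` is the allele of chromosome ``j`` at site ``i``: under
    ``coding="ref/alt"`` 1 means the ALT allele, under
    ``coding="ancestral/derived"`` 1 means the derived allele.
    ``sample_ids[j]`` names the diploid individual that chromosome ``j``
    belongs to; the two chromosomes of a sample are adjacent.
    """

    sites: list[VariantSite]
    data: np.ndarray
    sample_ids: list[str]
    coding: str = "ref/alt"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (sites x chromosomes)")
        if self.data.shape != (len(self.sites), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.data.shape} inconsistent with {len(self.sites)} sites "
                f"x {len(self.sample_ids)} chromosomes"
            )
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1 (missing not allowed)")
        pos = [s.pos for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("sites must be strictly increasing by position")
        if self.coding not in ("ref/alt", "ancestral/derived"):
            raise ValueError(f"unknown coding {self.coding!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_chromosomes(self) -> int:
        return self.data.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chromosomes_of(self, sample_ids) -> np.ndarray:
        wanted = set(sample_ids)
        return np.array([j for j, s in enumerate(self.sample_ids) if s in wanted], dtype=np.intp)

    def subset_chromosomes(self, idx) -> "HaplotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return replace(
            self, data=self.data[:, idx], sample_ids=[self.sample_ids[j] for j in idx]
        )

    def subset_samples(self, sample_ids) -> "HaplotypeMatrix":
        return self.subset_chromosomes(self.chromosomes_of(sample_ids))

    def subset_sites(self, idx) -> "HaplotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return replace(self, sites=[self.sites[i] for i in idx], data=self.data[idx, :])


@dataclass
class GenotypeMatrix:
    """Individuals x sites dosage matrix; entries in {0, 1, 2} or -1 missing."""

    sites: list[VariantSite]
    data: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"shape {self.data.shape} inconsistent with {len(self.sample_ids)} "
                f"individuals x {len(self.sites)} sites"
            )
        if self.data.size and not np.isin(self.data, (0, 1, 2, MISSING_DOSAGE)).all():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            self.sites, self.data[idx, :], [self.sample_ids[j] for j in idx]
        )

    def subset_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix([self.sites[i] for i in idx], self.data[:, idx], list(self.sample_ids))
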