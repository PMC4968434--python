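"""Readers/writers for the standard formats the pipeline touches.

VCF (phased GT, via cyvcf2), BED regions, TSV sample panels, per-site
ancestral-allele TSV or outgroup FASTA, and GML / edge-TSV haplotype
networks.  Internal coordinates are 0-based half-open; VCF is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .core import GenotypeMatrix, HaplotypeMatrix, PopulationPanel, Region, VariantSite

log = logging.getLogger(__name__)


def read_bed(path) -> list[Region]:
    """Read BED3+ into Regions (BED is already 0-based half-open)."""
    regions = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else f"region{k + 1}"
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), name))
    return regions


def read_ancestral_tsv(path) -> dict[tuple[str, int], str]:
    """Per-site ancestral alleles: CHROM, POS (1-based), AA columns."""
    anc: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("CHROM"):
                continue
            chrom, pos, aa = line.rstrip("\n").split("\t")[:3]
            anc[(chrom, int(pos) - 1)] = aa.upper()
    return anc


def read_outgroup_fasta(path, chrom: str, offset: int = 0) -> dict[tuple[str, int], str]:
    """Outgroup sequence aligned to the reference; base i maps to position offset+i."""
    from Bio import SeqIO  # local import: only needed for the FASTA route

    anc: dict[tuple[str, int], str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        for i, base in enumerate(str(rec.seq).upper()):
            if base in "ACGT":
                anc[(chrom, offset + i)] = base
        break
    return anc


def read_vcf_region(path, region: Region, panel: PopulationPanel) -> HaplotypeMatrix:
    """Load phased biallelic SNPs in ``region`` for the panel samples.

    Multiallelic and indel records are skipped (counted via the module
    logger).  Raises on unphased or missing genotypes: the phased matrix
    does not admit a missing code.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    missing = [s for s in panel.samples if s not in vcf_samples]
    if missing:
        raise ValueError(f"panel samples absent from VCF: {missing[:5]}")
    col = np.array([vcf_samples.index(s) for s in panel.samples])

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    # full scan + in-region filter: works on plain-text VCFs without an index
    for rec in vcf:
        pos0 = rec.POS - 1
        if not region.contains(rec.CHROM, pos0):
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(rec.genotype.array())[col]  # (n_samples, 3): a0, a1, phased
        if (gts[:, 2] == 0).any():
            bad = panel.samples[int(np.nonzero(gts[:, 2] == 0)[0][0])]
            raise ValueError(f"unphased genotype for sample {bad} at {rec.CHROM}:{rec.POS}")
        alleles = gts[:, :2]
        if (alleles < 0).any():
            bad = panel.samples[int(np.nonzero((alleles < 0).any(axis=1))[0][0])]
            raise ValueError(f"missing genotype for sample {bad} at {rec.CHROM}:{rec.POS}")
        sites.append(
            VariantSite(rec.CHROM, pos0, rec.ID or f"{rec.CHROM}:{rec.POS}", rec.REF, rec.ALT[0])
        )
        rows.append(alleles.reshape(-1))
    if n_skipped:
        log.info("read_vcf_region: skipped %d non-biallelic-SNP records", n_skipped)

    sample_ids = [s for s in panel.samples for _ in range(2)]
    data = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(sample_ids)), np.int8)
    H = HaplotypeMatrix(sites, data, sample_ids, coding="ref/alt")
    H.n_skipped_records = n_skipped
    return H


def write_vcf(H: HaplotypeMatrix, path) -> None:
    """Write a phased matrix back out as minimal VCF 4.2 text."""
    samples = H.sample_ids[::2]
    if H.sample_ids != [s for s in samples for _ in range(2)]:
        raise ValueError("chromosomes must pair adjacently by sample to write VCF")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in H.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, site in enumerate(H.sites):
            if H.coding == "ancestral/derived":
                # re-express in ref/alt orientation for the file
                anc = site.ancestral_allele
                ref, alt = site.ref_allele, site.alt_allele
                row = H.data[i] if anc == ref else 1 - H.data[i]
            else:
                row = H.data[i]
            gts = "\t".join(f"{row[2 * j]}|{row[2 * j + 1]}" for j in range(len(samples)))
            info = f"AA={site.ancestral_allele}" if site.ancestral_allele else "."
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t{site.id}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def polarize(
    H: HaplotypeMatrix,
    ancestral: dict[tuple[str, int], str],
    min_fraction: float = 0.9,
) -> HaplotypeMatrix:
    """Recode to ancestral/derived (1 = derived allele).

    Sites whose ancestral allele is unknown or matches neither observed
    allele are dropped (count available as ``n_dropped`` on the result).
    Raises if fewer than ``min_fraction`` of sites carry a usable
    ancestral call.
    """
    if H.coding == "ancestral/derived":
        return H
    keep, sites, cols = [], [], []
    for i, site in enumerate(H.sites):
        aa = ancestral.get((site.chrom, site.pos))
        if aa == site.ref_allele:
            sites.append(replace(site, ancestral_allele=aa))
            cols.append(H.data[i])
            keep.append(i)
        elif aa == site.alt_allele:
            sites.append(replace(site, ancestral_allele=aa))
            cols.append(1 - H.data[i])
            keep.append(i)
        else:
            log.info("polarize: dropping site %s (ancestral %r unusable)", site.id, aa)
    n_dropped = H.n_sites - len(keep)
    if H.n_sites and len(keep) < min_fraction * H.n_sites:
        raise ValueError(
            f"only {len(keep)}/{H.n_sites} sites polarizable "
            f"(< required fraction {min_fraction})"
        )
    data = np.array(cols, dtype=np.int8) if cols else np.empty((0, H.n_chromosomes), np.int8)
    out = HaplotypeMatrix(sites, data, list(H.sample_ids), coding="ancestral/derived")
    out.n_dropped = n_dropped
    return out


def to_genotypes(H: HaplotypeMatrix) -> GenotypeMatrix:
    """Collapse phased chromosomes into per-individual allele dosages."""
    cols_of: dict[str, list[int]] = {}
    for j, sid in enumerate(H.sample_ids):
        cols_of.setdefault(sid, []).append(j)
    for s, cols in cols_of.items():
        if len(cols) != 2:
            raise ValueError(f"sample {s} has {len(cols)} chromosomes, need 2")
    samples = list(cols_of)
    dosage = np.zeros((len(samples), H.n_sites), dtype=np.int8)
    for k, s in enumerate(samples):
        dosage[k] = H.data[:, cols_of[s]].sum(axis=1)
    return GenotypeMatrix(list(H.sites), dosage, samples)


def write_network(net, path, format: str = "gml") -> None:
    """Serialize an MJNetwork as GML or edge-TSV.  See network.read_network."""
    from . import network as _network

    if not isinstance(net, _network.MJNetwork) or not net.graph.number_of_nodes():
        raise ValueError("write_network requires a nonempty MJNetwork")
    if format == "gml":
        _network.write_gml(net, path)
    elif format == "edge-tsv":
        _network.write_edge_tsv(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "gml"):
    from . import network as _network

    if format == "gml":
        return _network.read_gml(path)
    elif format == "edge-tsv":
        return _network.read_edge_tsv(path)
    raise ValueError(f"unknown network format {format!r}")
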