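"""Readers and writers for the standard formats the pipeline touches.

Everything downstream works on four in-memory containers: a
:class:`VariantSet` (biallelic SNP sites x accessions), a list of
:class:`GeneModel` (merged CDS intervals), a :class:`PopulationPartition`
(population label and landrace/modern-variety status per accession) and a
:class:`PhenotypeTable` (accession x trait, missing-aware).

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
VCF (1-based positions) are converted at this boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("gchap")

#: genotype codes used throughout: ref hom, alt hom, heterozygous, missing
GT_REF, GT_ALT, GT_HET, GT_MISS = "0", "1", "H", "."


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class FormatError(InputError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class Site:
    """One biallelic SNP site; ``pos`` is 1-based as printed in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class GeneModel:
    """A gene's CDS footprint: non-overlapping, sorted 0-based half-open intervals."""

    gene_id: str
    chrom: str
    strand: str = "+"
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.cds_intervals = _merge_intervals(self.cds_intervals)

    def contains(self, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(s <= p < e for s, e in self.cds_intervals)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class VariantSet:
    """Biallelic SNP genotypes, one single-character code per accession x site.

    ``genotypes`` is an (n_accessions, n_sites) array over
    ``{"0", "1", "H", "."}`` (ref hom / alt hom / het / missing).
    """

    sites: list[Site]
    accessions: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype="<U1")
        if self.genotypes.shape != (len(self.accessions), len(self.sites)):
            raise InputError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.sites)} sites"
            )
        seen = set()
        for s in self.sites:
            key = (s.chrom, s.pos)
            if key in seen:
                raise InputError(f"duplicate site {key}")
            seen.add(key)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def subset_sites(self, indices: Sequence[int]) -> "VariantSet":
        idx = list(indices)
        return VariantSet(
            sites=[self.sites[i] for i in idx],
            accessions=list(self.accessions),
            genotypes=self.genotypes[:, idx] if idx else
            np.empty((self.n_accessions, 0), dtype="<U1"),
        )


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    if len(alts) != 1:
        return False
    alt = alts[0]
    return (
        len(ref) == 1 and len(alt) == 1
        and ref in "ACGT" and alt in "ACGT"
    )


def read_vcf(path: str | Path, region_filter: Sequence[GeneModel] | None = None) -> VariantSet:
    """Read a VCF v4.x file into a :class:`VariantSet`.

    Only biallelic SNP records are retained; multi-allelic records and
    indels are dropped (the dropped count is logged).  Genotypes are read
    unphased: ``0/0 -> "0"``, ``1/1 -> "1"``, ``0/1 -> "H"``, ``./. -> "."``.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped).
    region_filter
        If given, keep only sites whose position falls inside some CDS
        interval of one of these genes.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"VCF {path} has zero samples")

    code = {0: GT_REF, 1: GT_HET, 2: GT_ALT, 3: GT_MISS}
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        if not _is_biallelic_snp(rec.REF, rec.ALT):
            n_dropped += 1
            continue
        if region_filter is not None and not any(
            g.chrom == rec.CHROM and g.contains(rec.POS) for g in region_filter
        ):
            continue
        sites.append(Site(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        columns.append(np.array([code[t] for t in rec.gt_types], dtype="<U1"))
    vcf.close()
    if n_dropped:
        logger.info("read_vcf(%s): dropped %d non-biallelic-SNP records", path, n_dropped)

    genotypes = (
        np.column_stack(columns) if columns
        else np.empty((len(samples), 0), dtype="<U1")
    )
    return VariantSet(sites=sites, accessions=samples, genotypes=genotypes)


def write_vcf(variants: VariantSet, path: str | Path) -> None:
    """Write a :class:`VariantSet` as minimal VCF v4.2 with GT-only genotypes."""
    gt_text = {GT_REF: "0/0", GT_ALT: "1/1", GT_HET: "0/1", GT_MISS: "./."}
    chroms = []
    for s in variants.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.accessions) + "\n"
        )
        order = sorted(range(variants.n_sites),
                       key=lambda i: (chroms.index(variants.sites[i].chrom),
                                      variants.sites[i].pos))
        for i in order:
            s = variants.sites[i]
            gts = "\t".join(gt_text[g] for g in variants.genotypes[:, i])
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene CDS models from GFF3 or BED.

    GFF3 CDS features (1-based inclusive) are grouped by their ``Parent``
    attribute (falling back to ``ID`` / ``gene_id``); BED lines
    (0-based half-open) are grouped by the name column.  Either way the
    result uses the internal 0-based half-open convention with per-gene
    intervals merged and sorted.  A gene mentioned without any CDS feature
    is retained with an empty interval list (with a warning).
    """
    fmt = format.lower()
    if fmt not in {"gff3", "bed"}:
        raise InputError(f"unknown gene-model format {format!r}")
    genes: dict[str, GeneModel] = {}

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "gff3":
                if len(fields) < 9:
                    raise FormatError(f"{path}: GFF3 line with <9 columns: {line[:80]}")
                chrom, _, ftype, start, end, _, strand, _, attrs_text = fields[:9]
                attrs = _parse_gff3_attributes(attrs_text)
                gid = attrs.get("Parent") or attrs.get("gene_id") or attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}: feature without Parent/ID: {line[:80]}")
                gid = gid.split(",")[0]
                strand = strand if strand in "+-" else "+"
                if gid not in genes:
                    genes[gid] = GeneModel(gid, chrom, strand, [])
                if ftype == "CDS":
                    # GFF3 is 1-based inclusive
                    genes[gid].cds_intervals.append((int(start) - 1, int(end)))
            else:
                if len(fields) < 4:
                    raise FormatError(f"{path}: BED line needs >=4 columns: {line[:80]}")
                chrom, start, end, gid = fields[:4]
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
                if gid not in genes:
                    genes[gid] = GeneModel(gid, chrom, strand, [])
                genes[gid].cds_intervals.append((int(start), int(end)))

    out = []
    for g in genes.values():
        g.cds_intervals = _merge_intervals(g.cds_intervals)
        if not g.cds_intervals:
            logger.warning("gene %s has no CDS feature; retained empty", g.gene_id)
        out.append(g)
    return out


def write_gene_models_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for start, end in g.cds_intervals:
                fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


LAN, MV, UNKNOWN = "LAN", "MV", "unknown"


@dataclass
class PopulationPartition:
    """Per-accession population label and breeding status (LAN/MV/unknown)."""

    population: dict[str, str]
    breeding_status: dict[str, str]
    subpopulation: dict[str, str] = field(default_factory=dict)

    def members(self, population: str) -> list[str]:
        ids = [a for a, p in self.population.items() if p == population]
        if not ids:
            raise InputError(f"population {population!r} is empty or unknown")
        return ids

    def scope(self, population: str | None = None, status: str | None = None) -> list[str]:
        """Accessions matching a population and/or breeding status."""
        ids = [
            a for a in self.population
            if (population is None or self.population[a] == population)
            and (status is None or self.breeding_status.get(a, UNKNOWN) == status)
        ]
        if not ids:
            raise InputError(f"scope (population={population}, status={status}) is empty")
        return ids

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.population.values():
            if p not in seen:
                seen.append(p)
        return seen


def read_population_metadata(path: str | Path) -> PopulationPartition:
    """Read an accession metadata TSV (columns: accession, population,
    breeding_status, optional subpopulation)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "population", "breeding_status"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
    if df["accession"].duplicated().any():
        dups = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise InputError(f"{path}: duplicate accession rows: {dups[:5]}")
    status = {
        a: (s if s in {LAN, MV} else UNKNOWN)
        for a, s in zip(df["accession"], df["breeding_status"].fillna(UNKNOWN))
    }
    part = PopulationPartition(
        population=dict(zip(df["accession"], df["population"])),
        breeding_status=status,
    )
    if "subpopulation" in df.columns:
        part.subpopulation = dict(zip(df["accession"], df["subpopulation"].fillna("")))
    return part


def write_population_metadata(part: PopulationPartition, path: str | Path) -> None:
    rows = []
    for a in part.population:
        row = {
            "accession": a,
            "population": part.population[a],
            "breeding_status": part.breeding_status.get(a, UNKNOWN),
        }
        if part.subpopulation:
            row["subpopulation"] = part.subpopulation.get(a, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class PhenotypeTable:
    """Accession x trait numeric values; NaN marks missing."""

    values: pd.DataFrame  # index = accession, columns = traits
    units: dict[str, str] = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise InputError(f"unknown trait {name!r}")
        return self.values[name]


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV: first column accession, remaining columns numeric
    traits, empty cells missing.  A non-numeric non-empty cell is an error
    naming its row and column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "accession":
        df = df.rename(columns={df.columns[0]: "accession"})
    df = df.set_index("accession")
    if df.columns.duplicated().any():
        raise InputError(f"{path}: duplicate trait columns")
    out = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (df[col].str.strip() != "") & numeric.isna()
        if bad.any():
            acc = df.index[bad][0]
            raise InputError(
                f"{path}: non-numeric value {df.loc[acc, col]!r} "
                f"at accession {acc!r}, trait {col!r}"
            )
        out[col] = numeric
    values = pd.DataFrame(out, index=df.index)
    if np.isinf(values.to_numpy(dtype=float, na_value=np.nan)).any():
        raise InputError(f"{path}: non-finite phenotype value")
    return PhenotypeTable(values=values)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="accession", na_rep="")
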