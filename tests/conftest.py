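import textwrap

import numpy as np
import pandas as pd
import pytest

from gchap import GeneModel, Site, VariantSet, call_gchaps


def make_variantset(strings, accessions=None, chrom="chr1", start_pos=100,
                    ref="A", alt="T"):
    """Build a VariantSet from per-accession genotype-code strings
    (characters over {0,1,H,.}); all sites share ref/alt bases."""
    n_sites = len(strings[0])
    accs = accessions or [f"acc{i+1}" for i in range(len(strings))]
    sites = [Site(chrom, start_pos + i, ref, alt) for i in range(n_sites)]
    geno = np.array([list(s) for s in strings], dtype="<U1") if n_sites else \
        np.empty((len(accs), 0), dtype="<U1")
    return VariantSet(sites=sites, accessions=accs, genotypes=geno)


def write_vcf_text(path, records, samples=("s1", "s2")):
    """Write a small VCF; records are (chrom, pos, ref, alt, [gt strings])."""
    header = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##contig=<ID=chr1>
        """)
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    lines = [header + cols]
    for chrom, pos, ref, alt, gts in records:
        gt = "\t".join(gts)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def simple_table():
    """4 accessions, 2 sites: haplotypes AA, AA, AT, TT -> Hap1..Hap3."""
    vs = make_variantset(["00", "00", "01", "11"])
    return call_gchaps(vs, gene_id="g1")


@pytest.fixture
def two_pop_partition():
    from gchap import PopulationPartition

    return PopulationPartition(
        population={"acc1": "P1", "acc2": "P1", "acc3": "P2", "acc4": "P2"},
        breeding_status={"acc1": "LAN", "acc2": "LAN", "acc3": "MV", "acc4": "MV"},
    )
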