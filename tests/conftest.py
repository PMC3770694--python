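"""Shared fixtures: programmatic alignments, panels and file writers."""

from __future__ import annotations

import numpy as np
import pytest

from tyrscan.io import Alignment, HaplotypePanel, RegionInterval


def make_alignment(seqs, pops=None, outgroup=None, regions=None,
                   genomic_start=1):
    """Alignment from a list of equal-length strings."""
    mat = np.array([list(s) for s in seqs], dtype="U1")
    n, L = mat.shape
    if regions is None:
        regions = [RegionInterval(0, L, "5'flank")]
    return Alignment(
        sample_ids=[f"s{i}" for i in range(n)],
        pop_labels=pops or ["pop0"] * n,
        seqs=mat,
        outgroup=np.array(list(outgroup), dtype="U1") if outgroup else None,
        outgroup_id="chimp" if outgroup else None,
        genomic_start=genomic_start,
        regions=regions,
    )


def make_panel(geno, pos_bp=None, pops=None, cm_per_mb=1.0, chrom="1"):
    """HaplotypePanel from a 0/1/-1 matrix."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    pos = np.arange(1, m + 1) * 1000 if pos_bp is None else np.asarray(pos_bp)
    return HaplotypePanel(
        hap_ids=[f"h{i}" for i in range(n)],
        pop_labels=pops or ["pop0"] * n,
        geno=geno, pos_bp=pos, pos_cM=pos * cm_per_mb * 1e-6,
        chrom=np.full(m, chrom, dtype=object))


def write_alignment_inputs(tmp_path, seqs, pops, outgroup=None,
                           regions_text=None):
    """Write FASTA + metadata (+ annotation) files; return their paths."""
    fasta = tmp_path / "aln.fasta"
    lines = []
    for i, s in enumerate(seqs):
        lines.append(f">s{i}\n{s}")
    if outgroup is not None:
        lines.append(f">chimp\n{outgroup}")
    fasta.write_text("\n".join(lines) + "\n")

    meta = tmp_path / "meta.tsv"
    rows = ["sample\tpopulation\toutgroup"]
    for i, p in enumerate(pops):
        rows.append(f"s{i}\t{p}\t0")
    if outgroup is not None:
        rows.append("chimp\toutgroup\t1")
    meta.write_text("\n".join(rows) + "\n")

    ann = None
    if regions_text is not None:
        ann = tmp_path / "regions.tsv"
        ann.write_text(regions_text)
    return fasta, meta, ann


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def neutral_panel():
    """A moderate neutral panel shared by selscan/haplonet tests."""
    from tyrscan import coalsim
    model = coalsim.DemographicModel.constant(
        20_000, mutation_rate=1e-8, recombination_rate=1e-8)
    rep = coalsim.simulate_neutral(model, 500_000, seed=42, samples=60)
    return rep.to_panel(cm_per_mb=1.0)
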