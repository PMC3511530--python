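import pytest

from tfrctx.model import AnnotationBundle, GeneRecord, Replicon


def make_replicon(genes, length=None, topology="linear", sequence=None, rid="chr1"):
    """Replicon from (locus, strand, start, end[, product]) tuples."""
    records = []
    for t in genes:
        locus, strand, start, end = t[:4]
        product = t[4] if len(t) > 4 else ""
        records.append(GeneRecord(rid, locus, strand, start, end, "CDS", product))
    if length is None:
        length = max(g.end for g in records) + 100
    return Replicon(rid, length, topology, sequence, records)


def make_bundle(genes, **kwargs):
    return AnnotationBundle([make_replicon(genes, **kwargs)])


@pytest.fixture
def three_gene_replicon():
    return make_replicon(
        [("A", "+", 100, 400), ("B", "-", 600, 900), ("C", "+", 1200, 1500)]
    )
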