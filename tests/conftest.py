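import pytest

from probetrack.simulate import (
    ExpressionConfig,
    SimulationConfig,
    generate_expression,
    generate_panel,
)


@pytest.fixture(scope="session")
def sim_data():
    """Shared synthetic fixture with every planted scenario."""
    return generate_panel(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def sim_annotations(sim_data):
    return sim_data.annotation_sets()


@pytest.fixture(scope="session")
def sim_expression(sim_data):
    return generate_expression(sim_data.truth, ExpressionConfig(), seed=7)


# -- tiny hand-written annotation fixtures -----------------------------------

TOY_GFF3 = """##gff-version 3
chr1\ttoy\tgene\t1\t100\t.\t+\t.\tID=gene:G1;gene_id=G1;gene_name=ALPHA;gene_type=protein_coding
chr1\ttoy\ttranscript\t1\t60\t.\t+\t.\tID=tx:T1;Parent=gene:G1;transcript_id=T1;gene_id=G1;gene_name=ALPHA;transcript_type=protein_coding
chr1\ttoy\texon\t1\t30\t.\t+\t.\tID=exon:T1.1;Parent=tx:T1
chr1\ttoy\texon\t41\t60\t.\t+\t.\tID=exon:T1.2;Parent=tx:T1
chr1\ttoy\ttranscript\t1\t100\t.\t+\t.\tID=tx:T2;Parent=gene:G1;transcript_id=T2;gene_id=G1;gene_name=ALPHA;transcript_type=protein_coding
chr1\ttoy\texon\t1\t100\t.\t+\t.\tID=exon:T2.1;Parent=tx:T2
"""

TOY_GTF = """chr1\ttoy\tgene\t1\t100\t.\t+\t.\tgene_id "G1"; gene_name "ALPHA"; gene_type "protein_coding";
chr1\ttoy\ttranscript\t1\t60\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_name "ALPHA"; transcript_type "protein_coding";
chr1\ttoy\texon\t1\t30\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; exon_number "1";
chr1\ttoy\texon\t41\t60\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; exon_number "2";
chr1\ttoy\ttranscript\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T2"; gene_name "ALPHA"; transcript_type "protein_coding";
chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T2"; exon_number "1";
"""


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path
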