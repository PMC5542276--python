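import numpy as np
import pytest

from dirgenerank import ClinicalTable, ExpressionMatrix, PPIEdgeList


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, 5.0, 5.0, 5.0],
                [2.0, 7.0, 7.0, 1.0],
            ]
        ),
    )


@pytest.fixture
def tiny_clinical():
    return ClinicalTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        days=np.array([800.0, 1500.0, 900.0, 1200.0]),
        dead=np.array([True, False, False, True]),
    )


@pytest.fixture
def tiny_ppi():
    return PPIEdgeList([("g1", "g2"), ("g1", "g3")])


def write_expression_tsv(path, gene_ids, sample_ids, values):
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
        for g, row in zip(gene_ids, values):
            fh.write(g + "\t" + "\t".join(str(v) for v in row) + "\n")
    return path
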