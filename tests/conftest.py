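import pandas as pd
import pytest

from codonscope import STANDARD_CODE, CONDITIONS
from codonscope.expression import ExpressionMatrix
from codonscope.sequences import OrfRecord, OrfSet


def make_cds(*rna_codons: str, pad_to: int | None = None) -> str:
    """Build a DNA coding sequence from RNA codons, optionally padded with
    GCT repeats (before any terminal stop) up to ``pad_to`` codons."""
    codons = [c.replace("U", "T") for c in rna_codons]
    if pad_to is not None and len(codons) < pad_to:
        stop = codons.pop() if codons[-1] in ("TAA", "TAG", "TGA") else None
        codons += ["GCT"] * (pad_to - len(codons) - (1 if stop else 0))
        if stop:
            codons.append(stop)
    return "".join(codons)


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def tiny_orfs() -> OrfSet:
    """Three hand-built 100-codon ORFs with distinct codon usage."""
    return OrfSet([
        OrfRecord("orfA", make_cds("AUG", "GCU", "UAA", pad_to=100)),
        OrfRecord("orfB", make_cds("AUG", "GAA", "GAA", "GAG", "UAG", pad_to=100)),
        OrfRecord("orfC", make_cds("AUG", "CGA", "CGA", "UGA", pad_to=100),
                  is_ribosomal=True),
    ])


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    df = pd.DataFrame(
        [[2.0, 4.0, 8.0, 16.0],
         [50.0, 50.0, 50.0, 50.0],
         [200.0, 400.0, 1200.0, 300.0]],
        index=["orfA", "orfB", "orfC"],
        columns=list(CONDITIONS),
    )
    return ExpressionMatrix(df)
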