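import numpy as np
import pandas as pd
import pytest

from cytoreg import MotifSet, synth
from cytoreg.nanostring import NanoStringPanel


@pytest.fixture
def arr1_motifs() -> MotifSet:
    """The extended type-B response-regulator binding motif, expanded."""
    return MotifSet("arr1-extended", frozenset({"AAGATTTT", "AAGATCTT"}))


@pytest.fixture
def toy_genome(tmp_path):
    """A 60-gene toy genome on 2 contigs with full promoter clearance."""
    contigs, genes = synth.make_toy_genome(
        60, n_contigs=2, window=200, seed=11
    )
    fasta = tmp_path / "genome.fa"
    synth.write_genome_fasta(contigs, fasta)
    return contigs, genes, fasta


def make_panel(counts: dict[str, list[float]], lanes=("T1", "T2", "C1", "C2")):
    """Hand-built panel: probe classes inferred from probe-id prefixes."""
    index = list(counts)
    df = pd.DataFrame(
        np.array(list(counts.values()), dtype=float), index=index, columns=lanes
    )
    classes = pd.Series(
        [
            "positive" if p.startswith("POS") else
            "negative" if p.startswith("NEG") else
            "reference" if p.startswith("REF") else "endogenous"
            for p in index
        ],
        index=index,
    )
    condition = {l: ("treated" if l.startswith("T") else "control") for l in lanes}
    return NanoStringPanel(
        counts=df, probe_class=classes, lane_condition=condition
    )


@pytest.fixture
def flat_panel():
    """All-identical lanes: every scale factor must be exactly 1."""
    return make_panel(
        {
            "geneA": [100, 100, 100, 100],
            "geneB": [400, 400, 400, 400],
            "POS_A": [800, 800, 800, 800],
            "POS_B": [200, 200, 200, 200],
            "NEG_A": [4, 4, 4, 4],
            "NEG_B": [6, 6, 6, 6],
            "REF_1": [500, 500, 500, 500],
        }
    )
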