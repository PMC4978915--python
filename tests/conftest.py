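import numpy as np
import pandas as pd
import pytest

from sdrscan.io import (
    BIPARENTAL,
    MATERNAL,
    PATERNAL,
    GenotypeMatrix,
    MarkerLocus,
)
from sdrscan.simulate import CrossDesign, design_from_dict, simulate_population


def make_locus(marker_id="m1", chromosome="chr01", cM=0.0, Mb=0.0,
               seg_class=PATERNAL, phase_m=None, phase_p=None):
    if phase_m is None and seg_class in (MATERNAL, BIPARENTAL):
        phase_m = 0
    if phase_p is None and seg_class in (PATERNAL, BIPARENTAL):
        phase_p = 0
    return MarkerLocus(
        marker_id=marker_id, chromosome=chromosome, genetic_pos=cM,
        physical_pos=Mb, seg_class=seg_class,
        phase_maternal=phase_m, phase_paternal=phase_p,
    )


def make_matrix(loci, columns, progeny_ids=None):
    """Build a GenotypeMatrix from loci and per-locus code lists."""
    n = len(columns[0])
    progeny_ids = progeny_ids or [f"P{i+1:03d}" for i in range(n)]
    codes = pd.DataFrame(
        {l.marker_id: col for l, col in zip(loci, columns)},
        index=progeny_ids, dtype=object,
    )
    return GenotypeMatrix(progeny_ids=progeny_ids, loci=list(loci), codes=codes)


@pytest.fixture
def tiny_matrix():
    """3 progeny x 2 markers, one maternal and one paternal locus."""
    loci = [
        make_locus("mA", "chr01", 0.0, 0.0, MATERNAL),
        make_locus("mB", "chr01", 5.0, 2.0, PATERNAL),
    ]
    return make_matrix(loci, [["ll", "lm", "ll"], ["np", "np", "nn"]])


@pytest.fixture
def null_design():
    """No-selection mixed design on two chromosomes."""
    return design_from_dict({
        "n_progeny": 200,
        "seed": 11,
        "chromosomes": [
            {"name": "chr01", "length_cM": 60, "length_Mb": 50, "seg_class": "mixed"},
            {"name": "chr02", "length_cM": 40, "length_Mb": 30, "seg_class": "paternal"},
        ],
    })


@pytest.fixture
def null_population(null_design):
    return simulate_population(null_design)
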