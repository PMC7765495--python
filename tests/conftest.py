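import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from consenseq.preprocess import CountMatrix, SampleSheet

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def make_sheet(treatments=("SB", "DMSO"), timepoints=(3, 6, 9), n_reps=3,
               anchors=True) -> SampleSheet:
    rows = []
    for trt in treatments:
        for t in timepoints:
            for r in range(1, n_reps + 1):
                rows.append((f"{trt}_{t}h_r{r}", trt, t, r))
    if anchors:
        for t in (0, max(timepoints)):
            for r in range(1, n_reps + 1):
                rows.append((f"untreated_{t}h_r{r}", "untreated", t, r))
    return SampleSheet(pd.DataFrame(rows, columns=["sample", "treatment", "timepoint_h", "replicate"]))


def make_counts(sheet: SampleSheet, n_genes=20, seed=0, lam=50.0) -> CountMatrix:
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(lam, size=(n_genes, len(sheet.sample_ids))),
        index=pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id"),
        columns=sheet.sample_ids,
    )
    return CountMatrix(counts)


@pytest.fixture
def toy_sheet():
    return make_sheet()


@pytest.fixture
def toy_counts(toy_sheet):
    return make_counts(toy_sheet)
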