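import numpy as np
import pandas as pd
import pytest

import qpcrmine as q
from qpcrmine.ctio import OIL_FEATURES


@pytest.fixture(scope="session")
def table1():
    return q.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return q.load_fixture("table2")


@pytest.fixture(scope="session")
def oils(table1):
    return table1.subset(list(OIL_FEATURES))


@pytest.fixture()
def small_ct_csv(tmp_path):
    """A tiny 2-treatment, 2-replicate, 1-target, 1-reference Ct table."""
    text = (
        "sample,peg,pro,replicate,gene,role,ct\n"
        "s1,0,0,1,tgt,target,25.0\n"
        "s1,0,0,1,ref,reference,20.0\n"
        "s2,0,0,2,tgt,target,25.4\n"
        "s2,0,0,2,ref,reference,20.4\n"
        "s3,10,0,1,tgt,target,23.0\n"
        "s3,10,0,1,ref,reference,20.0\n"
        "s4,10,0,2,tgt,target,23.2\n"
        "s4,10,0,2,ref,reference,20.2\n"
    )
    path = tmp_path / "ct.csv"
    path.write_text(text)
    return path


CT_COLUMN_MAP = {
    "sample": "sample",
    "treatment": ["peg", "pro"],
    "replicate": "replicate",
    "gene": "gene",
    "role": "role",
    "ct": "ct",
}


@pytest.fixture()
def ct_column_map():
    return dict(CT_COLUMN_MAP)


def make_synth_spec(seed=0, folds=(0.25, 1, 4, 16), n_replicates=3, well_noise_sd=0.2,
                    references=None, **kwargs):
    """A 3x5 two-reference experiment with folds cycled over ``folds``."""
    base = q.SynthSpec()
    mapping = q.fold_grid(base.treatments(), base.control, folds, seed)
    extra = {} if references is None else {"reference_genes": references}
    return q.SynthSpec(
        true_folds={"geneA": mapping},
        n_replicates=n_replicates,
        well_noise_sd=well_noise_sd,
        seed=seed,
        **extra,
        **kwargs,
    )
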