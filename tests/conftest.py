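import numpy as np
import pandas as pd
import pytest

from epiedit.arraydm import BetaMatrix, ProbeManifest
from epiedit.simulate import make_tsdr_fixture


@pytest.fixture(scope="session")
def tsdr_design():
    return make_tsdr_fixture()


@pytest.fixture()
def small_manifest():
    """100 probes on two chromosomes; gene G has 10 probes, others 5 or none."""
    rows = []
    gene_assign = {}
    # gene G: probes 0..9; genes H1..H14: 5 probes each (10..79); 80..99 unannotated
    for i in range(10):
        gene_assign[i] = ("G",)
    for k in range(14):
        for j in range(5):
            gene_assign[10 + 5 * k + j] = (f"H{k + 1:02d}",)
    for i in range(100):
        chrom = "chr1" if i < 60 else "chr2"
        pos = (i if i < 60 else i - 60) * 100 + 50
        rows.append({"chrom": chrom, "pos": pos, "genes": gene_assign.get(i, ())})
    table = pd.DataFrame(
        rows, index=pd.Index([f"cg{i:08d}" for i in range(100)], name="probe_id")
    )
    return ProbeManifest(table)


@pytest.fixture()
def small_beta(small_manifest):
    rng = np.random.default_rng(7)
    n = len(small_manifest)
    baseline = rng.uniform(0.2, 0.8, n)
    cols = {}
    groups = {}
    for g in ("ctrl", "treat"):
        for r in range(3):
            name = f"{g}_{r + 1}"
            cols[name] = np.clip(baseline + rng.normal(0, 0.01, n), 0, 1)
            groups[name] = g
    values = pd.DataFrame(cols, index=small_manifest.probe_ids)
    return BetaMatrix(values, groups)
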