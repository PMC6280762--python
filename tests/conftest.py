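import numpy as np
import pytest

from clonesift.config import (
    CallConfig,
    CloneConfig,
    DepthConfig,
    ErrorModelConfig,
    LayoutConfig,
    PanelConfig,
    RunConfig,
)
from clonesift.synthetic import (
    build_error_model,
    build_layout,
    build_panel,
    place_clones,
    simulate_pileups,
)
from clonesift.types import Amplicon, AmpliconPanel


@pytest.fixture(scope="session")
def default_panel():
    return build_panel(PanelConfig(), seed=7)


@pytest.fixture(scope="session")
def default_layout():
    return build_layout(LayoutConfig(), seed=7)


@pytest.fixture(scope="session")
def tiny_amplicon():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    return Amplicon(
        amplicon_id="AMP_T", gene="G1", pathway="OTHER", chrom="chr1",
        start=0, end=100, fwd_primer_len=20, rev_primer_len=20, sequence=seq,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_amplicon):
    return AmpliconPanel([tiny_amplicon])


@pytest.fixture(scope="session")
def spiked_run():
    """48-sample run with one clear clone per testis; used by several modules."""
    seed = 3
    panel = build_panel(PanelConfig(), seed=seed)
    sheet, bmap = build_layout(LayoutConfig(), seed=seed)
    clone_cfg = CloneConfig(n_clones=4, vaf_range=(0.008, 0.02), vaf_decay=0.8)
    truth = place_clones(panel, bmap, clone_cfg, seed=seed)
    em = build_error_model(panel, sheet, ErrorModelConfig(), seed=seed)
    pileup = simulate_pileups(panel, sheet, truth, em, DepthConfig(), seed=seed)
    return {
        "panel": panel, "sheet": sheet, "bmap": bmap,
        "truth": truth, "pileup": pileup, "seed": seed,
    }
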