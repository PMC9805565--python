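import numpy as np
import pytest

from smurf.smooth_align import AlignParams


def all_mode_params(temperature=1.0):
    """All eight {local,global} x {linear,affine} x restrict_turns combos."""
    out = []
    for mode in ("local", "global"):
        for rt in (True, False):
            out.append(AlignParams(temperature=temperature, gap=-1.3,
                                   gap_mode="linear", align_mode=mode,
                                   restrict_turns=rt))
            out.append(AlignParams(temperature=temperature, open=-2.1,
                                   extend=-0.4, gap_mode="affine",
                                   align_mode=mode, restrict_turns=rt))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_family():
    """A small synthetic family shared across tests (cheap to generate)."""
    from smurf.synthetic import generate_family
    return generate_family(L=14, n_contacts=4, strength=2.0, n_seqs=60,
                           sweeps=15, ins_rate=0.05, del_rate=0.05, seed=42)
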