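"""Shared fixtures: expensive simulated objects are session-scoped."""

import numpy as np
import pytest

from oscinfer import inversion, regressors, stimgen, synthlfp, tfreg


@pytest.fixture(scope="session")
def model_space():
    return inversion.build_model_space()


@pytest.fixture(scope="session")
def run8000(model_space):
    """Full-length simulated sequence and its ideal-observer inversion."""
    seq = stimgen.generate_sequence(8000, rng=12345)
    regs = inversion.compute_regressors(seq, model_space)
    return seq, regs


@pytest.fixture(scope="session")
def analysis600(model_space):
    """A complete synthetic analysis at reduced scale: 600 segments,
    3 channels, default effects, 100 permutations per regressor."""
    seq = stimgen.generate_sequence(600, rng=98765)
    regs = inversion.compute_regressors(seq, model_space)
    part = regressors.partialise(regs)
    rec = synthlfp.generate_recording(regs, n_channels=3, rng=424242)
    tf = tfreg.morlet_decompose(rec)
    tfidx = {s: i for i, s in enumerate(tf.segments)}
    common = [s for s in part.segments if s in tfidx]
    keep_idx = np.array([tfidx[s] for s in common])
    maps = {}
    for name in regressors.REGRESSOR_COLUMNS:
        x = part.frame.loc[common, name].to_numpy()
        maps[name] = tfreg.regress_with_permutations(
            tf, x, n_perm=100, alpha=0.05, rng=777, keep_segments=keep_idx
        )
    return {
        "seq": seq,
        "regs": regs,
        "part": part,
        "rec": rec,
        "tf": tf,
        "common": common,
        "keep_idx": keep_idx,
        "maps": maps,
    }
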