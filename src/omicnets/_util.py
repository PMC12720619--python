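"""Shared helpers: sample-id conventions and seeded random streams."""

from __future__ import annotations

import numpy as np

# Sample identifiers follow "SUBJ<k>-V<j>" (subject, vial). Everything before
# the final "-V<digits>" suffix is the subject id, so subject ids themselves
# may contain dashes.
_VIAL_SEP = "-V"


def subject_of(sample_id: str) -> str:
    """Return the subject id encoded in a ``SUBJ<k>-V<j>`` sample id.

    A sample id without a vial suffix is its own subject id.
    """
    head, sep, tail = sample_id.rpartition(_VIAL_SEP)
    if sep and tail.isdigit():
        return head
    return sample_id


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministically split one seed into ``n`` independent generators.

    Each consumer (layer, stage, replicate) gets its own stream so that adding
    one consumer does not perturb the draws of the others.
    """
    ss = np.random.SeedSequence(int(seed))
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n)]


def derive_seed(seed: int, index: int) -> int:
    """Derive a reproducible 31-bit sub-seed for run ``index``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
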