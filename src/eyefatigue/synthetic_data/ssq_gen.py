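"""Synthetic SSQ item responses linked to the latent fatigue trajectory.

First-epoch responses are identically zero (subjects start fully relaxed);
later responses are sparse ordinal scores whose rates grow with latent
fatigue, with the "eye fatigue" item the most responsive.
"""

from __future__ import annotations

import numpy as np

from eyefatigue.ssq_scoring import SSQ_ITEMS

#: Per-item Poisson rate multipliers on positive latent fatigue.
_ITEM_RATES = {name: 0.12 for name in SSQ_ITEMS}
_ITEM_RATES["eye_fatigue"] = 0.5
_ITEM_RATES["fatigue"] = 0.25
_ITEM_RATES["difficulty_focusing"] = 0.2


def generate_ssq_responses(f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Item scores of shape (n_subjects, epochs, 16), each in {0..3}."""
    n, epochs = f.shape
    rates = np.array([_ITEM_RATES[name] for name in SSQ_ITEMS])
    lam = np.clip(f, 0.0, None)[:, :, None] * rates[None, None, :]
    scores = np.minimum(rng.poisson(lam), 3)
    scores[:, 0, :] = 0  # fully relaxed baseline by protocol
    return scores.astype(int)
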