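"""Two-stage z-scoring that removes first- and second-order non-stationarity.

Stage 1 z-scores each channel within each single trial, making amplitudes
comparable across trials.  Stage 2 z-scores each (channel, sample) cell
across the trials of a condition, which removes the evoked (ERP) component
and cross-trial variance differences: after stage 2 the per-condition trial
average is identically zero.  The order of the two stages is fixed.

Both stages use the sample (n-1 denominator) standard deviation.  Zero
variance anywhere raises :class:`~eegstates.data.DegenerateInputError`
rather than emitting NaN, because silent NaNs would corrupt the downstream
autoregressive fits.
"""

from __future__ import annotations

import numpy as np

from .data import DegenerateInputError, TrialTensor

__all__ = ["zscore_within_trial", "zscore_across_trials", "preprocess"]


def zscore_within_trial(t: TrialTensor) -> TrialTensor:
    """Z-score every channel x trial series over its samples.

    Returns a new tensor in which each (channel, trial) series has mean 0
    and sample standard deviation 1.
    """
    data = t.data
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=1, keepdims=True)
    bad = np.nonzero(sd[:, 0, :] == 0)
    if bad[0].size:
        ch, tr = bad[0][0], bad[1][0]
        raise DegenerateInputError(
            f"constant series: channel {ch} ({t.channel_names[ch]}), trial {tr}"
        )
    return t.copy_with((data - mu) / sd)


def zscore_across_trials(t: TrialTensor) -> TrialTensor:
    """Z-score each (channel, sample) cell across trials, per condition.

    The cross-trial mean (the ERP, per condition) is removed and the
    cross-trial standard deviation normalized to 1.
    """
    out = np.empty_like(t.data)
    for label in t.conditions():
        mask = t.condition == label
        block = t.data[:, :, mask]
        mu = block.mean(axis=2, keepdims=True)
        sd = block.std(axis=2, ddof=1, keepdims=True)
        if np.any(sd == 0):
            ch, sm = np.nonzero(sd[:, :, 0] == 0)
            raise DegenerateInputError(
                f"zero cross-trial variance in condition {label!r} at "
                f"channel {ch[0]}, sample {sm[0]}"
            )
        out[:, :, mask] = (block - mu) / sd
    return t.copy_with(out)


def preprocess(t: TrialTensor) -> TrialTensor:
    """Within-trial z-scoring followed by across-trial z-scoring."""
    return zscore_across_trials(zscore_within_trial(t))
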