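"""Predictive-coding segment layer: prediction, state and error units.

Each segment in the inventory is one channel in a bank of units.
Prediction units ("P") carry the top-down prior — the lexically derived
next-segment distribution deposited on its channels.  State units ("S")
carry the bottom-up likelihood — unit mass on the heard segment.  Both
densities may be blurred by a Gaussian tuning kernel over channel index
distance (width 0 means delta tuning).  Prediction-error units ("PE")
encode the channelwise absolute difference between the two densities.

With width 0 the aggregate PE activity equals the summed-absolute segment
prediction error exactly, so the unit-level model reduces to the
ideal-observer measure in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from lexicohort.lexicon import Lexicon, Segment, Transcription
from lexicohort.measures import next_segment_distribution, timecourse


class ChannelError(ValueError):
    """Raised when a segment has no channel or inventories mismatch."""


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian tuning width over channel-index distance.

    ``width`` is the standard deviation in channel units; 0 selects
    identity (delta) tuning.  Smoothing uses reflecting boundaries so the
    total activity of a density is conserved.
    """

    width: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError(f"kernel width must be >= 0: {self.width}")


def _smooth(activity: np.ndarray, kernel: KernelConfig) -> np.ndarray:
    if kernel.width == 0:
        return activity
    return gaussian_filter1d(activity, sigma=kernel.width, mode="reflect")


def _channel_index(
    inventory: Sequence[Segment],
) -> dict[Segment, int]:
    index = {seg: i for i, seg in enumerate(inventory)}
    if len(index) != len(inventory):
        raise ChannelError("inventory contains duplicate segments")
    return index


def prior_density(
    prediction: Mapping[Segment, float],
    inventory: Sequence[Segment],
    kernel: KernelConfig = KernelConfig(),
) -> np.ndarray:
    """Prediction-unit activity: the next-segment distribution on channels.

    Each predicted segment's probability is deposited on its channel and
    convolved with the tuning kernel; total activity is preserved.
    """
    index = _channel_index(inventory)
    activity = np.zeros(len(inventory))
    for seg, p in prediction.items():
        if seg not in index:
            raise ChannelError(f"predicted segment {seg!r} not in inventory")
        activity[index[seg]] += p
    return _smooth(activity, kernel)


def likelihood_density(
    heard: Segment,
    inventory: Sequence[Segment],
    kernel: KernelConfig = KernelConfig(),
) -> np.ndarray:
    """State-unit activity: unit mass on the heard segment's channel."""
    index = _channel_index(inventory)
    if heard not in index:
        raise ChannelError(f"heard segment {heard!r} not in inventory")
    activity = np.zeros(len(inventory))
    activity[index[heard]] = 1.0
    return _smooth(activity, kernel)


@dataclass(frozen=True)
class SegmentUnitBank:
    """Joint state of the three unit populations over one inventory."""

    inventory: tuple[Segment, ...]
    prior: np.ndarray  # prediction units, P
    likelihood: np.ndarray  # state units, S
    error: np.ndarray  # prediction-error units, PE

    @property
    def aggregate_error(self) -> float:
        """Total PE activity summed over channels."""
        return float(self.error.sum())


def prediction_error_activity(
    prior: np.ndarray,
    likelihood: np.ndarray,
    inventory: Sequence[Segment],
) -> SegmentUnitBank:
    """PE-unit activity: channelwise |prior - likelihood|."""
    prior = np.asarray(prior, dtype=float)
    likelihood = np.asarray(likelihood, dtype=float)
    if prior.shape != likelihood.shape or prior.shape != (len(inventory),):
        raise ChannelError(
            f"density shapes {prior.shape}/{likelihood.shape} do not match "
            f"inventory of {len(inventory)} channels"
        )
    return SegmentUnitBank(
        inventory=tuple(inventory),
        prior=prior,
        likelihood=likelihood,
        error=np.abs(prior - likelihood),
    )


def default_inventory(
    lexicon: Lexicon, *extra: Sequence[Segment]
) -> tuple[Segment, ...]:
    """Sorted segment inventory covering a lexicon plus extra sequences."""
    segments: set[Segment] = set()
    for entry in lexicon:
        segments.update(entry.transcription)
    for seq in extra:
        segments.update(seq)
    return tuple(sorted(segments))


def simulate_word_pe(
    lexicon: Lexicon,
    stimulus: Transcription,
    kernel: KernelConfig = KernelConfig(),
    inventory: Sequence[Segment] | None = None,
) -> list[SegmentUnitBank]:
    """Unit-bank series across a stimulus, one bank per segment position.

    At each position the prior comes from the lexical next-segment
    distribution over the heard prefix and the likelihood from the arriving
    segment.  With ``kernel.width == 0`` the aggregate PE series equals the
    ideal-observer prediction-error timecourse exactly (an empty cohort
    yields a flat zero prior, so each later segment contributes 1).
    """
    if inventory is None:
        inventory = default_inventory(lexicon, stimulus)
    tc = timecourse(lexicon, stimulus)
    banks: list[SegmentUnitBank] = []
    for t in range(len(tc)):
        prior = prior_density(tc.prediction[t], inventory, kernel)
        likelihood = likelihood_density(tc.stimulus[t], inventory, kernel)
        banks.append(prediction_error_activity(prior, likelihood, inventory))
    return banks
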