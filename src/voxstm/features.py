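"""Recording-to-feature transformer tying the front end together."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import AudioRecording, Cohort
from .filterbank import FilterbankSpec, auditory_spectrogram
from .stm import stm_frame_features

__all__ = ["STMFeaturizer", "featurize_cohort"]


class STMFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: waveform -> per-frame STM feature vectors.

    ``transform`` accepts a list of ``(waveform, sample_rate)`` pairs or
    :class:`AudioRecording` objects and returns the vertically stacked
    frame features; per-recording frame counts are exposed in
    ``frame_counts_`` after the call.  Under the default
    :class:`FilterbankSpec` each 15-s frame yields 22,528 features.
    """

    def __init__(self, spec: FilterbankSpec | None = None, frame_length: float = 15.0):
        self.spec = spec
        self.frame_length = frame_length

    def fit(self, X=None, y=None):
        return self

    def _one(self, rec) -> np.ndarray:
        spec = self.spec or FilterbankSpec()
        if isinstance(rec, AudioRecording):
            wave, sr = rec.waveform, rec.sample_rate
        else:
            wave, sr = rec
        sgram = auditory_spectrogram(wave, sr, spec)
        return stm_frame_features(sgram, spec, frame_length=self.frame_length)

    def transform(self, X) -> np.ndarray:
        feats = [self._one(rec) for rec in X]
        self.frame_counts_ = [f.shape[0] for f in feats]
        d = (self.spec or FilterbankSpec()).n_features
        return np.vstack(feats) if feats else np.empty((0, d))


def featurize_cohort(
    cohort: Cohort,
    spec: FilterbankSpec | None = None,
    frame_length: float = 15.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Extract frame features for every recording of a cohort.

    Returns the stacked feature matrix and a frame-level metadata table
    (participant_id, session_index, state, time_of_day, sss, frame_id)
    aligned row-for-row with it.  Recordings are synthesised and
    featurised one at a time, so memory stays bounded.
    """
    featurizer = STMFeaturizer(spec=spec, frame_length=frame_length)
    blocks, meta_rows = [], []
    for rec in cohort.recordings():
        f = featurizer._one(rec)
        blocks.append(f)
        for k in range(f.shape[0]):
            meta_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "session_index": rec.session_index,
                    "state": rec.state,
                    "time_of_day": rec.time_of_day,
                    "sss": rec.sss,
                    "frame_id": k,
                }
            )
    d = (spec or FilterbankSpec()).n_features
    X = np.vstack(blocks) if blocks else np.empty((0, d))
    return X, pd.DataFrame(meta_rows)
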