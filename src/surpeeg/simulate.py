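"""Synthetic multi-subject EEG epochs with known injected effects.

Stands in for recorded data: epochs are time-locked to word onsets
(-0.3 to 1.0 s), and each predictor can contribute a rank-one
spatio-temporal pattern — a spatial weight per electrode times a Gaussian
temporal kernel — scaled by the predictor's per-word value and a per-subject
gain.  Added noise is temporally smoothed Gaussian (AR(1)), which gives the
cluster permutation test a realistic temporal-correlation challenge while
keeping every generating parameter known for recovery tests.

Simulated amplitudes are exactly linear in every predictor (holding the
others fixed), mirroring the regression model that will be fit to them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .grammar import POSCorpus
from .montage import Montage
from .surprisal import SurprisalSeries

__all__ = [
    "Effect",
    "EffectSpec",
    "EpochSet",
    "build_predictor_table",
    "simulate_epochs",
    "lowpass_epochs",
    "reject_trials",
    "effect_amplitude_for_snr",
]

#: epoch window in seconds relative to word onset
EPOCH_WINDOW = (-0.3, 1.0)

#: simulated log-frequency distributions per word class.  Function words are
#: far more frequent than content words; values emulate log HAL-style counts.
LOGFREQ_PARAMS = {"content": (8.0, 2.0), "function": (12.0, 1.5)}


@dataclass(frozen=True)
class Effect:
    """One injected rank-one spatio-temporal effect of a predictor.

    ``spatial`` holds one weight per electrode; the temporal kernel is a
    Gaussian bump ``amplitude * exp(-(t - center)^2 / (2 width^2))`` whose
    center must lie inside the epoch window.  ``word_class`` optionally
    restricts the effect to content or function words.
    """

    predictor: str
    spatial: np.ndarray
    center: float  # s
    width: float  # s
    amplitude: float
    word_class: str | None = None

    def kernel(self, times: np.ndarray) -> np.ndarray:
        if not (EPOCH_WINDOW[0] <= self.center <= EPOCH_WINDOW[1]):
            raise ValueError(
                f"kernel center {self.center} s outside epoch window {EPOCH_WINDOW}"
            )
        if not np.isfinite(self.amplitude):
            raise ValueError("effect amplitude must be finite")
        return self.amplitude * np.exp(
            -0.5 * ((times - self.center) / self.width) ** 2
        )


EffectSpec = list  # a spec is simply a list of Effect entries


@dataclass
class EpochSet:
    """subjects x words x electrodes x samples amplitude array.

    ``times`` runs from -0.3 to 1.0 s at sampling rate ``fs``; sample count
    is round(1.3 * fs) + 1 with time 0 aligned to word onset.  ``mask`` marks
    per-subject retained trials.
    """

    data: np.ndarray  # (S, W, E, T)
    times: np.ndarray  # (T,)
    fs: float
    montage: Montage
    mask: np.ndarray  # (S, W) bool

    def __post_init__(self) -> None:
        expect_t = int(round((EPOCH_WINDOW[1] - EPOCH_WINDOW[0]) * self.fs)) + 1
        if self.data.shape[3] != expect_t or len(self.times) != expect_t:
            raise ValueError(
                f"expected {expect_t} samples at fs={self.fs}, "
                f"got {self.data.shape[3]}"
            )
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask must be (subjects, words)")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_words(self) -> int:
        return self.data.shape[1]

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    # -- persistence (binary container + JSON sidecar) ---------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, chunks=True)
            f.create_dataset("mask", data=self.mask)
        sidecar = {
            "fs": self.fs,
            "times": self.times.tolist(),
            "montage": {
                "names": list(self.montage.names),
                "positions": self.montage.positions.tolist(),
                "adjacency": self.montage.adjacency.astype(int).tolist(),
            },
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text(encoding="utf-8")
        )
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            mask = f["mask"][()].astype(bool)
        montage = Montage(
            names=tuple(meta["montage"]["names"]),
            positions=np.array(meta["montage"]["positions"]),
            adjacency=np.array(meta["montage"]["adjacency"], dtype=bool),
        )
        return cls(
            data=data,
            times=np.array(meta["times"]),
            fs=float(meta["fs"]),
            montage=montage,
            mask=mask,
        )


def epoch_times(fs: float) -> np.ndarray:
    n = int(round((EPOCH_WINDOW[1] - EPOCH_WINDOW[0]) * fs)) + 1
    return EPOCH_WINDOW[0] + np.arange(n) / fs


# ---------------------------------------------------------------------------
# predictor table


def build_predictor_table(
    corpus: POSCorpus,
    surprisals: list[SurprisalSeries],
    seed: int = 0,
) -> pd.DataFrame:
    """One row per corpus word: orders, simulated covariates, surprisals.

    Covariates emulate the control predictors of the single-trial analysis:
    sentence order, word order within sentence, log word frequency of the
    current/previous/following word (Gaussian per word class; the story is
    treated as continuous, so the shifted columns cross sentence boundaries
    and the two story edges are filled with the overall mean), and sound
    power at word onset (standard normal).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for si, sent in enumerate(corpus.sentences):
        for wi, tag in enumerate(sent):
            rows.append(
                {
                    "sentence_order": si + 1,
                    "word_order": wi + 1,
                    "tag": tag,
                    "word_class": corpus.word_class_map[tag],
                }
            )
    df = pd.DataFrame(rows)
    mu = df["word_class"].map({k: v[0] for k, v in LOGFREQ_PARAMS.items()})
    sd = df["word_class"].map({k: v[1] for k, v in LOGFREQ_PARAMS.items()})
    df["frq"] = rng.normal(mu.to_numpy(float), sd.to_numpy(float))
    grand = df["frq"].mean()
    df["frq_prev"] = df["frq"].shift(1, fill_value=grand)
    df["frq_next"] = df["frq"].shift(-1, fill_value=grand)
    df["sound_power"] = rng.normal(0.0, 1.0, len(df))
    for s in surprisals:
        if len(s) != len(df):
            raise ValueError(f"series {s.model_name!r} not aligned to corpus")
        df[f"surprisal_{s.model_name}"] = s.values
    return df


# ---------------------------------------------------------------------------
# epoch synthesis


def simulate_epochs(
    table: pd.DataFrame,
    effects: list[Effect],
    montage: Montage,
    n_subjects: int,
    fs: float = 500.0,
    noise_sd: float = 1.0,
    ar_coef: float = 0.3,
    subject_gain_sd: float = 0.2,
    seed: int = 0,
) -> EpochSet:
    """Generate epochs: sum of injected rank-one effects plus AR(1) noise.

    amplitude(s, w, e, t) =
        sum_eff x(w) * spatial(e) * kernel(t) * gain(s) + noise(s, w, e, t)

    with gain(s) ~ N(1, subject_gain_sd) and noise marginally N(0, noise_sd)
    with lag-1 temporal autocorrelation ``ar_coef``.  Fully deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    times = epoch_times(fs)
    W = len(table)
    E = montage.n_electrodes
    T = len(times)

    signal_part = np.zeros((W, E, T))
    for eff in effects:
        if eff.predictor not in table.columns:
            raise ValueError(f"effect predictor {eff.predictor!r} not in table")
        if len(eff.spatial) != E:
            raise ValueError("spatial weights must have one entry per electrode")
        x = table[eff.predictor].to_numpy(float).copy()
        if eff.word_class is not None:
            x = np.where(table["word_class"] == eff.word_class, x, 0.0)
        kern = eff.kernel(times)
        signal_part += (
            x[:, None, None] * np.asarray(eff.spatial)[None, :, None] * kern[None, None, :]
        )

    gains = rng.normal(1.0, subject_gain_sd, n_subjects)
    data = gains[:, None, None, None] * signal_part[None]

    if noise_sd > 0:
        white = rng.normal(0.0, 1.0, (n_subjects, W, E, T))
        if ar_coef != 0.0:
            innov_sd = noise_sd * np.sqrt(1.0 - ar_coef**2)
            noise = signal.lfilter([1.0], [1.0, -ar_coef], innov_sd * white, axis=-1)
        else:
            noise = noise_sd * white
        data = data + noise

    mask = np.ones((n_subjects, W), dtype=bool)
    return EpochSet(data=data, times=times, fs=fs, montage=montage, mask=mask)


def effect_amplitude_for_snr(
    snr: float, predictor_sd: float, noise_sd: float, max_spatial: float = 1.0
) -> float:
    """Kernel amplitude so the peak effect sd equals ``snr`` times noise sd."""
    return snr * noise_sd / (predictor_sd * max_spatial)


def lowpass_epochs(epochs: EpochSet, cutoff: float) -> EpochSet:
    """Zero-phase 4th-order Butterworth low-pass; no baseline correction.

    The filter is applied forward-backward, squaring the single-pass
    magnitude response (gain 1/sqrt(2) at the cutoff becomes 1/2).
    """
    if cutoff >= epochs.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({epochs.fs / 2})")
    sos = signal.butter(4, cutoff, btype="low", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(
        data=filtered,
        times=epochs.times,
        fs=epochs.fs,
        montage=epochs.montage,
        mask=epochs.mask,
    )


def reject_trials(epochs: EpochSet, fraction: float, seed: int = 0) -> EpochSet:
    """Randomly drop an expected ``fraction`` of trials per subject."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("rejection fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random((epochs.n_subjects, epochs.n_words)) >= fraction
    return EpochSet(
        data=epochs.data,
        times=epochs.times,
        fs=epochs.fs,
        montage=epochs.montage,
        mask=epochs.mask & keep,
    )
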