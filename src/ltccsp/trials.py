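"""Containers for epoched multichannel EEG trials and text serialization.

A :class:`Trial` is one epoch: an ``N x S`` matrix (channels x samples).
A :class:`TrialSet` is an ordered collection of trials with per-trial class
labels in ``{1, 2}`` and a shared sampling rate.  On disk a trial set is a
manifest CSV (columns ``trial_file, label, fs``) plus one plain CSV matrix
per trial — deliberately language-neutral and diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["Trial", "TrialSet", "read_trialset", "write_trialset"]

VALID_LABELS = (1, 2)

_CHANNELS_FILE = "channels.txt"


def _default_channel_names(n: int) -> list[str]:
    return [f"ch{i + 1}" for i in range(n)]


@dataclass
class Trial:
    """One epoched trial: ``data`` is channels x samples, in whatever units
    the recording came in (metadata only; nothing downstream rescales)."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"trial data must be 2-D (channels x samples), got ndim={self.data.ndim}"
            )
        n, s = self.data.shape
        if n < 2 or s < 2:
            raise ValidationError(
                f"trial needs >=2 channels and >=2 samples, got {n}x{s}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("trial data contains non-finite values (NaN/Inf)")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = _default_channel_names(n)
        elif len(self.channel_names) != n:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {n} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Ordered trials with labels in {1, 2}; all trials share N, S, fs and
    channel order.  Label 1 is "class X" (the class whose projected variance
    the filters maximize), label 2 is "class Y"."""

    trials: list[Trial]
    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.trials) == 0:
            raise ValidationError("trial set is empty")
        if self.labels.shape != (len(self.trials),):
            raise ValidationError(
                f"{self.labels.size} labels for {len(self.trials)} trials"
            )
        bad = set(self.labels.tolist()) - set(VALID_LABELS)
        if bad:
            raise ValidationError(f"labels outside {{1, 2}}: {sorted(bad)}")
        ref = self.trials[0]
        for k, t in enumerate(self.trials):
            if t.data.shape != ref.data.shape:
                raise ValidationError(
                    f"trial {k} has shape {t.data.shape}, expected {ref.data.shape}"
                )
            if t.fs != self.fs:
                raise ValidationError(
                    f"trial {k} has fs={t.fs}, trial set declares fs={self.fs}"
                )
            if t.channel_names != ref.channel_names:
                raise ValidationError(f"trial {k} has different channel order/names")

    @classmethod
    def from_arrays(
        cls,
        data: np.ndarray,
        labels: Sequence[int],
        fs: float,
        channel_names: Sequence[str] | None = None,
    ) -> "TrialSet":
        """Build a trial set from a stacked ``(K, N, S)`` array."""
        data = np.asarray(data, dtype=float)
        if data.ndim != 3:
            raise ValidationError(f"expected (K, N, S) array, got ndim={data.ndim}")
        names = list(channel_names) if channel_names else _default_channel_names(data.shape[1])
        trials = [Trial(data[k], fs=fs, channel_names=list(names)) for k in range(data.shape[0])]
        return cls(trials=trials, labels=np.asarray(labels, dtype=int), fs=fs)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def channel_names(self) -> list[str]:
        return self.trials[0].channel_names

    @property
    def data(self) -> np.ndarray:
        """Stacked ``(K, N, S)`` view (copy) of all trials."""
        return np.stack([t.data for t in self.trials])

    def class_count(self, label: int) -> int:
        return int(np.sum(self.labels == label))

    def subset(self, indices: Iterable[int]) -> "TrialSet":
        idx = list(indices)
        return TrialSet(
            trials=[self.trials[i] for i in idx],
            labels=self.labels[idx],
            fs=self.fs,
        )

    def trials_of(self, label: int) -> list[Trial]:
        return [t for t, l in zip(self.trials, self.labels) if l == label]

    def require_both_classes(self) -> None:
        for label in VALID_LABELS:
            if self.class_count(label) < 1:
                raise ValidationError(
                    f"fitting requires both classes; class {label} has no trials"
                )


def read_trialset(manifest_path: str | Path) -> TrialSet:
    """Load a trial set from a manifest CSV.

    The manifest has columns ``trial_file, label, fs``; ``trial_file`` paths
    are resolved relative to the manifest's directory.  Each trial file is a
    plain CSV of floats, rows = channels, columns = samples.  A
    ``channels.txt`` file (one name per line) next to the manifest, if
    present, supplies channel names.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"trial_file", "label", "fs"}
    if not required.issubset(manifest.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, got {list(manifest.columns)}"
        )
    if len(manifest) == 0:
        raise ValidationError(f"manifest lists no trials: {manifest_path}")
    fs_values = manifest["fs"].unique()
    if len(fs_values) != 1:
        raise ValidationError(f"manifest mixes sampling rates: {fs_values.tolist()}")
    fs = float(fs_values[0])

    base = manifest_path.parent
    names: list[str] = []
    ch_file = base / _CHANNELS_FILE
    if ch_file.exists():
        names = [ln.strip() for ln in ch_file.read_text().splitlines() if ln.strip()]

    trials: list[Trial] = []
    for _, row in manifest.iterrows():
        path = base / str(row["trial_file"])
        if not path.exists():
            raise FileNotFoundError(f"trial file not found: {path}")
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        try:
            trials.append(Trial(data, fs=fs, channel_names=list(names)))
        except ValidationError as exc:
            raise ValidationError(f"trial file {path.name}: {exc}") from exc
    labels = manifest["label"].to_numpy()
    try:
        labels = labels.astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"labels must be integers in {{1, 2}}: {exc}") from exc
    return TrialSet(trials=trials, labels=labels, fs=fs)


def write_trialset(ts: TrialSet, out_dir: str | Path) -> Path:
    """Write a trial set; returns the manifest path.  ``%.17g`` formatting
    keeps the text round trip below 1e-12 relative error."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    width = max(3, len(str(ts.n_trials)))
    for k, trial in enumerate(ts.trials):
        fname = f"trial_{k:0{width}d}.csv"
        np.savetxt(out_dir / fname, trial.data, delimiter=",", fmt="%.17g")
        rows.append({"trial_file": fname, "label": int(ts.labels[k]), "fs": ts.fs})
    (out_dir / _CHANNELS_FILE).write_text("\n".join(ts.channel_names) + "\n")
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
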