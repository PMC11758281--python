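"""Core epoch containers, amplitude clipping, downsampling, and file I/O.

An *epoch* is a fixed-length multichannel EEG segment time-locked to one
stimulus: a channels x time matrix of amplitudes in microvolt (uV).  The
default geometry is 64 channels by 60 time steps spanning -0.2 s to 1.0 s
around stimulus onset, i.e. one sample every ~20.34 ms, with onset at time
index 10.  Amplitudes are saturated to [-50, 50] uV.

The on-disk layout is deliberately language-neutral: one ``.npy`` array per
participant (epochs x channels x time) plus a single CSV metadata table with
one row per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

#: Saturation bounds for EEG amplitudes, in microvolt.
AMPLITUDE_LO: float = -50.0
AMPLITUDE_HI: float = 50.0

#: Default epoch geometry.
DEFAULT_N_CHANNELS: int = 64
DEFAULT_N_STEPS: int = 60
DEFAULT_ONSET_INDEX: int = 10
DEFAULT_EPOCH_DURATION_MS: float = 1200.0

#: Sentinel for a digit-less (empty-circle) distractor.
EMPTY: int = -1

#: Stimulus kinds and experimental conditions.
KINDS: tuple[str, ...] = ("Target", "Distractor")
CONDITIONS: tuple[str, ...] = ("C1", "C2", "C3", "C4")


class DataModelError(ValueError):
    """Raised on contract violations in epoch data or metadata."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    """One stimulus-locked EEG segment.

    Parameters
    ----------
    values
        Channels x time matrix of amplitudes in uV.
    onset_index
        Time index of stimulus onset (default 10, i.e. 0.2 s of
        pre-stimulus baseline at ~20.34 ms per step).
    """

    values: np.ndarray
    onset_index: int = DEFAULT_ONSET_INDEX

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataModelError(f"epoch values must be 2-D, got shape {values.shape}")
        if values.shape[0] < 1 or values.shape[1] < 2:
            raise DataModelError(
                f"epoch needs >=1 channel and >=2 time steps, got {values.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EpochMeta:
    """Per-epoch experimental metadata.

    ``digit`` is 0-9 or :data:`EMPTY` for a digit-less distractor; a Target
    always carries a digit.  ``position`` is 1-based within the sequence.
    ``attended`` and ``score`` are optional annotations filled in by the
    generator and the scoring stage respectively.
    """

    participant_id: str
    sequence_index: int
    position: int
    kind: str
    digit: int
    condition: str
    attended: bool | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DataModelError(f"unknown stimulus kind {self.kind!r}")
        if self.condition not in CONDITIONS:
            raise DataModelError(f"unknown condition {self.condition!r}")
        if not (self.digit == EMPTY or 0 <= self.digit <= 9):
            raise DataModelError(f"digit must be 0-9 or EMPTY, got {self.digit}")
        if self.kind == "Target" and self.digit == EMPTY:
            raise DataModelError("a Target stimulus must carry a digit")
        if self.position < 1:
            raise DataModelError(f"position is 1-based, got {self.position}")


@dataclass
class EpochSet:
    """A collection of epochs with aligned metadata.

    All epochs share the same channel and time geometry.  A full default
    experiment holds 1200 epochs per participant (30 sequences x 10 stimuli
    x 4 conditions).
    """

    epochs: list[tuple[Epoch, EpochMeta]] = field(default_factory=list)
    sampling_step_ms: float = 20.34

    def __post_init__(self) -> None:
        shapes = {ep.values.shape for ep, _ in self.epochs}
        if len(shapes) > 1:
            raise DataModelError(f"epochs disagree on shape: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, meta in self.epochs:
            seen.setdefault(meta.participant_id, None)
        return list(seen)

    def values_array(self) -> np.ndarray:
        """Stack all epochs into an (n_epochs, C, T) array."""
        if not self.epochs:
            return np.empty((0, 0, 0))
        return np.stack([ep.values for ep, _ in self.epochs])

    def metadata_frame(self) -> pd.DataFrame:
        """All metadata as a DataFrame, one row per epoch, in order."""
        return pd.DataFrame([_meta_to_record(m) for _, m in self.epochs])


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


def clip_amplitude(epoch: Epoch, lo: float = AMPLITUDE_LO, hi: float = AMPLITUDE_HI) -> Epoch:
    """Saturate amplitudes to ``[lo, hi]`` uV.

    Values outside the range are replaced by the nearest bound; the epoch
    count is preserved (saturation, not rejection).  Non-finite input is
    rejected with the offending (channel, time) index.
    """
    if not lo < hi:
        raise DataModelError(f"need lo < hi, got lo={lo}, hi={hi}")
    values = epoch.values
    bad = ~np.isfinite(values)
    if bad.any():
        c, t = np.argwhere(bad)[0]
        raise DataModelError(
            f"non-finite amplitude at channel {int(c)}, time step {int(t)}"
        )
    return replace(epoch, values=np.clip(values, lo, hi))


def downsample(series: np.ndarray, period: int) -> np.ndarray:
    """Keep every ``period``-th sample starting at index 0 (plain decimation).

    Output length is ``ceil(len(series) / period)``.  No anti-alias filter is
    applied: this is subsampling of an already low-passed signal.
    """
    if int(period) != period or period < 1:
        raise DataModelError(f"subsampling period must be a positive integer, got {period}")
    series = np.asarray(series)
    if series.shape[-1] < period:
        raise DataModelError(
            f"series of length {series.shape[-1]} shorter than period {period}"
        )
    return series[..., ::int(period)]


def time_step_ms(duration_ms: float = DEFAULT_EPOCH_DURATION_MS, n_steps: int = DEFAULT_N_STEPS) -> float:
    """Duration of one time step for ``n_steps`` samples spanning ``duration_ms``.

    The ``n_steps`` samples delimit ``n_steps - 1`` intervals, so the default
    1200 ms / 59 ~= 20.34 ms.
    """
    if n_steps < 2:
        raise DataModelError(f"need at least 2 time steps, got {n_steps}")
    return duration_ms / (n_steps - 1)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "participant_id",
    "sequence_index",
    "position",
    "kind",
    "digit",
    "condition",
    "attended",
    "score",
]


def _meta_to_record(meta: EpochMeta) -> dict:
    return {
        "participant_id": meta.participant_id,
        "sequence_index": meta.sequence_index,
        "position": meta.position,
        "kind": meta.kind,
        "digit": "" if meta.digit == EMPTY else meta.digit,
        "condition": meta.condition,
        "attended": "" if meta.attended is None else int(meta.attended),
        "score": "" if meta.score is None else meta.score,
    }


def _record_to_meta(row: pd.Series) -> EpochMeta:
    digit_raw = row["digit"]
    digit = EMPTY if (pd.isna(digit_raw) or digit_raw == "") else int(digit_raw)
    attended_raw = row.get("attended", "")
    attended = None if (pd.isna(attended_raw) or attended_raw == "") else bool(int(attended_raw))
    score_raw = row.get("score", "")
    score = None if (pd.isna(score_raw) or score_raw == "") else float(score_raw)
    return EpochMeta(
        participant_id=str(row["participant_id"]),
        sequence_index=int(row["sequence_index"]),
        position=int(row["position"]),
        kind=str(row["kind"]),
        digit=digit,
        condition=str(row["condition"]),
        attended=attended,
        score=score,
    )


def validate_positions(meta_frame: pd.DataFrame, seq_length: int = 10) -> None:
    """Check that every (participant, condition, sequence) covers positions 1..seq_length."""
    if meta_frame.empty:
        return
    grouped = meta_frame.groupby(["participant_id", "condition", "sequence_index"])
    for key, grp in grouped:
        positions = sorted(grp["position"].astype(int))
        if positions != list(range(1, seq_length + 1)):
            raise DataModelError(
                f"sequence {key} has positions {positions}, expected 1..{seq_length}"
            )


def write_epochset(epochset: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to ``path``: one ``<participant>.npy`` per participant
    plus ``metadata.csv`` (UTF-8, header row, EMPTY digit as empty string)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = epochset.metadata_frame()
    if meta.empty:
        meta = pd.DataFrame(columns=_META_COLUMNS)
    meta.to_csv(path / "metadata.csv", index=False, encoding="utf-8")
    with open(path / "sampling.txt", "w", encoding="utf-8") as fh:
        fh.write(f"{epochset.sampling_step_ms!r}\n")
    for pid in epochset.participants:
        arr = np.stack(
            [ep.values for ep, m in epochset.epochs if m.participant_id == pid]
        )
        np.save(path / f"{pid}.npy", arr)


def read_epochset(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochset`.

    Rejects shape mismatches between the per-participant arrays and the
    metadata rows; validates the 1..10 position invariant per sequence.
    """
    path = Path(path)
    meta = pd.read_csv(path / "metadata.csv", dtype={"participant_id": str}, keep_default_na=False)
    sampling_step = 20.34
    sampling_file = path / "sampling.txt"
    if sampling_file.exists():
        sampling_step = float(sampling_file.read_text().strip())
    epochs_by_row: dict[int, tuple[Epoch, EpochMeta]] = {}
    if not meta.empty:
        seq_length = int(meta["position"].astype(int).max())
        validate_positions(meta, seq_length=seq_length)
        for pid, grp in meta.groupby("participant_id", sort=False):
            arr = np.load(path / f"{pid}.npy")
            if arr.shape[0] != len(grp):
                raise DataModelError(
                    f"participant {pid}: array holds {arr.shape[0]} epochs, "
                    f"metadata lists {len(grp)}"
                )
            for i, (row_pos, row) in enumerate(grp.iterrows()):
                epochs_by_row[row_pos] = (Epoch(arr[i]), _record_to_meta(row))
    epochs = [epochs_by_row[i] for i in sorted(epochs_by_row)]
    return EpochSet(epochs=epochs, sampling_step_ms=sampling_step)
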