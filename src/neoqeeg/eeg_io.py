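"""EDF recording I/O, channel derivations, and clinical covariates.

The analysis montage is four channels recorded against a common
midline reference (F3, F4, P3, P4). Signals are analysed either as the
stored referential channels or as sample-wise bipolar differences
(e.g. F3-P3). The sedative-administration timepoint travels with each
recording, either as an EDF+ annotation labelled ``DEX`` or as a
column of the covariates table (the annotation wins when both exist).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf

REQUIRED_CHANNELS = ("F3", "F4", "P3", "P4")

REFERENTIAL_DERIVATIONS = ("F3", "F4", "P3", "P4")
BIPOLAR_DERIVATIONS = ("F3-P3", "F4-P4", "F3-F4", "P3-P4")
ALL_DERIVATIONS = REFERENTIAL_DERIVATIONS + BIPOLAR_DERIVATIONS

DRUG_ANNOTATION = "DEX"

_LABEL_RE = re.compile(r"^(?:EEG[ _-]*)?([A-Z]+\d*)(?:[ _-]*(?:REF|FZ|CZ|A1|A2))?$", re.I)


def normalize_label(label: str) -> str:
    """Map EDF label dialects ('EEG F3-Fz', 'f3-REF', ...) to 'F3'."""
    m = _LABEL_RE.match(label.strip())
    if m:
        return m.group(1).upper()
    return label.strip().upper()


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts with a drug-administration time.

    ``drug_time`` is in seconds from the start of the recording; all
    time intervals in the package are half-open ``[t0, t1)`` seconds.
    """

    samples: np.ndarray          # channels x time, uV
    sampling_rate: float         # Hz
    channel_labels: list[str]
    drug_time: float             # s from start
    subject_id: str = "unknown"
    start_time: object | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channel_labels]
        if missing:
            raise ValueError(f"missing required channel(s): {', '.join(missing)}")
        if not (0 < self.drug_time < self.duration):
            raise ValueError(
                f"drug_time {self.drug_time} s outside recording (0, {self.duration}) s"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.samples[idx]


@dataclass(frozen=True)
class Derivation:
    """A referential channel or a bipolar difference of two channels."""

    name: str
    lead_a: str
    lead_b: str | None = None  # None -> referential (common reference)

    @staticmethod
    def from_name(name: str) -> "Derivation":
        if name in REFERENTIAL_DERIVATIONS:
            return Derivation(name, name, None)
        if name in BIPOLAR_DERIVATIONS:
            a, b = name.split("-")
            return Derivation(name, a, b)
        raise ValueError(f"unknown derivation {name!r}; expected one of {ALL_DERIVATIONS}")


@dataclass
class ClinicalRecord:
    """Per-subject clinical covariates used by the cohort statistics."""

    subject_id: str
    gestational_age_days: float
    fentanyl: bool
    diagnosis_group: int
    drug_time: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (7 * 22 <= self.gestational_age_days <= 7 * 44):
            raise ValueError(
                f"gestational_age_days {self.gestational_age_days} outside plausible range"
            )
        if int(self.diagnosis_group) not in (0, 1, 2, 3):
            raise ValueError(f"diagnosis_group must be 0-3, got {self.diagnosis_group}")


def derive(rec: EEGRecording, d: Derivation | str) -> np.ndarray:
    """Return the single-channel signal for a derivation, in uV.

    Referential derivations return the stored channel unchanged (the
    montage is recorded against a common reference, so no
    re-referencing is applied); bipolar derivations are the sample-wise
    difference lead_a - lead_b.
    """
    if isinstance(d, str):
        d = Derivation.from_name(d)
    a = rec.channel(d.lead_a)
    if d.lead_b is None:
        return a.copy()
    return a - rec.channel(d.lead_b)


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as EDF+C with the drug time as a 'DEX' annotation."""
    return _edf.write_edf(
        path,
        rec.samples,
        rec.sampling_rate,
        rec.channel_labels,
        subject_id=rec.subject_id,
        annotations=[(float(rec.drug_time), None, DRUG_ANNOTATION)],
    )


def _read_edf_raw(path: str | Path):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mne.io.read_raw_edf(str(path), preload=True, verbose="error")


def read_recording(
    path: str | Path,
    covariates_path: str | Path | None = None,
    subject_id: str | None = None,
    expected_sampling_rate: float = 250.0,
) -> tuple[EEGRecording, ClinicalRecord | None]:
    """Read an EDF/EDF+ recording plus (optionally) its clinical sidecar.

    Channel labels are normalized (case-insensitive, 'EEG ' prefix and
    reference suffixes tolerated). The drug time is taken from the
    'DEX' EDF+ annotation when present, else from a ``drug_time_s``
    column of the covariates table.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    raw = _read_edf_raw(path)

    norm = {normalize_label(ch): ch for ch in raw.ch_names}
    missing = [c for c in REQUIRED_CHANNELS if c not in norm]
    if missing:
        raise ValueError(f"{path.name}: missing required channel(s): {', '.join(missing)}")

    fs = float(raw.info["sfreq"])
    if abs(fs - expected_sampling_rate) > 1e-6:
        warnings.warn(
            f"{path.name}: sampling rate {fs} Hz differs from the expected "
            f"{expected_sampling_rate} Hz; analyses are defined in seconds and proceed",
            stacklevel=2,
        )

    picks = [norm[c] for c in REQUIRED_CHANNELS]
    data_uv = raw.get_data(picks=picks) * 1e6  # mne returns volts

    drug_time = None
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.strip().upper() == DRUG_ANNOTATION:
            drug_time = float(onset)
            break

    clinical = None
    if covariates_path is not None:
        table = pd.read_csv(covariates_path)
        row = table.loc[table["subject_id"].astype(str) == str(subject_id)]
        if not row.empty:
            r = row.iloc[0]
            cov_drug = float(r["drug_time_s"]) if "drug_time_s" in row.columns else None
            clinical = ClinicalRecord(
                subject_id=str(subject_id),
                gestational_age_days=float(r["gestational_age_days"]),
                fentanyl=bool(int(r["fentanyl"])),
                diagnosis_group=int(r["diagnosis_group"]),
                drug_time=cov_drug,
            )
            if drug_time is None:
                drug_time = cov_drug

    if drug_time is None:
        raise ValueError(
            f"{path.name}: no drug-administration time (no 'DEX' annotation and no "
            "drug_time_s covariate)"
        )

    rec = EEGRecording(
        samples=data_uv,
        sampling_rate=fs,
        channel_labels=list(REQUIRED_CHANNELS),
        drug_time=drug_time,
        subject_id=str(subject_id),
        start_time=raw.info.get("meas_date"),
    )
    return rec, clinical


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the clinical covariates table (one row per subject)."""
    table = pd.read_csv(path)
    required = {"subject_id", "gestational_age_days", "fentanyl", "diagnosis_group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"covariates table missing columns: {sorted(missing)}")
    table["subject_id"] = table["subject_id"].astype(str)
    return table
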