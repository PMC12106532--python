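"""Event-matrix container, asinh transform, downsampling, concatenation.

All clustering and embedding operate on hyperbolic-arcsine transformed
intensities (``asinh(x / cofactor)``, cofactor 5 by convention in mass
cytometry) after random downsampling to a fixed number of events per
subject (50,000 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import as_rng

logger = logging.getLogger(__name__)

RAW, ASINH5 = "raw", "asinh5"
_LABEL_COLUMN = "__population"


@dataclass
class EventMatrix:
    """Single-subject events x markers matrix with provenance.

    ``scale`` is either ``"raw"`` (non-negative instrument intensities) or
    ``"asinh5"`` (transformed).  ``labels`` optionally carries the true
    population index per event (synthetic data only).
    """

    subject_id: str
    group: str
    markers: list[str]
    values: np.ndarray
    scale: str = RAW
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.markers):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.markers)} markers"
            )
        if self.scale not in (RAW, ASINH5):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == RAW and self.values.size and self.values.min() < 0:
            raise ValueError("raw intensities must be non-negative")
        if self.labels is not None and len(self.labels) != len(self.values):
            raise ValueError("labels length does not match event count")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.markers)
        if self.labels is not None:
            df[_LABEL_COLUMN] = self.labels
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path, subject_id=None, group="unknown", scale=RAW) -> "EventMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        labels = None
        if _LABEL_COLUMN in df.columns:
            labels = df.pop(_LABEL_COLUMN).to_numpy(dtype=int)
        return cls(
            subject_id=subject_id or path.stem,
            group=group,
            markers=list(df.columns),
            values=df.to_numpy(dtype=float),
            scale=scale,
            labels=labels,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """asinh cofactor, downsampling target and rule, and seed."""

    asinh_cofactor: float = 5.0
    events_per_subject: int = 50_000
    downsample_rule: str = "keep-all-if-fewer"  # or "strict"
    seed: int = 0

    def __post_init__(self):
        if self.asinh_cofactor <= 0:
            raise ValueError("asinh_cofactor must be positive")
        if self.events_per_subject < 1:
            raise ValueError("events_per_subject must be >= 1")
        if self.downsample_rule not in ("strict", "keep-all-if-fewer"):
            raise ValueError(f"unknown downsample_rule {self.downsample_rule!r}")


def asinh_transform(matrix: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Apply x -> asinh(x / cofactor).  Refuses already-transformed input."""
    if matrix.scale != RAW:
        raise ValueError(
            f"{matrix.subject_id}: input is already on {matrix.scale} scale"
        )
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return replace(matrix, values=np.arcsinh(matrix.values / cofactor), scale=ASINH5)


def inverse_asinh(matrix: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Analytic inverse: x -> sinh(x) * cofactor."""
    if matrix.scale != ASINH5:
        raise ValueError("input is not asinh-transformed")
    return replace(matrix, values=np.sinh(matrix.values) * cofactor, scale=RAW)


def downsample(matrix: EventMatrix, config: PreprocessConfig, rng=None) -> EventMatrix:
    """Uniform sampling without replacement to ``events_per_subject`` rows.

    Subjects with fewer events are kept in full under the default
    ``keep-all-if-fewer`` rule (with a logged warning) so that no subject
    is silently dropped; ``strict`` raises instead.
    """
    rng = as_rng(config.seed if rng is None else rng)
    target = config.events_per_subject
    n = matrix.n_events
    if n < target:
        if config.downsample_rule == "strict":
            raise ValueError(
                f"subject {matrix.subject_id} has {n} events, fewer than the "
                f"required {target}"
            )
        logger.warning(
            "subject %s has %d events (< %d); keeping all",
            matrix.subject_id, n, target,
        )
        return matrix
    idx = np.sort(rng.choice(n, size=target, replace=False))
    labels = matrix.labels[idx] if matrix.labels is not None else None
    return replace(matrix, values=matrix.values[idx], labels=labels)


def concatenate(matrices: list[EventMatrix]) -> pd.DataFrame:
    """Pool subject matrices into one events table with provenance columns.

    Returns a DataFrame with marker columns plus ``subject_id``, ``group``
    and (when every input carries labels) ``__population``.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    ref = matrices[0]
    bad = [m.subject_id for m in matrices if m.markers != ref.markers]
    if bad:
        raise ValueError(f"marker panel mismatch for subjects: {bad}")
    bad = [m.subject_id for m in matrices if m.scale != ref.scale]
    if bad:
        raise ValueError(f"scale mismatch for subjects: {bad}")
    frames = []
    with_labels = all(m.labels is not None for m in matrices)
    for m in matrices:
        df = pd.DataFrame(m.values, columns=m.markers)
        df["subject_id"] = m.subject_id
        df["group"] = m.group
        if with_labels:
            df[_LABEL_COLUMN] = m.labels
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    pooled.attrs["scale"] = ref.scale
    pooled.attrs["markers"] = list(ref.markers)
    return pooled


def preprocess_cohort(
    matrices: list[EventMatrix], config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Downsample, asinh-transform and pool a cohort (the standard order)."""
    config = config or PreprocessConfig()
    rng = as_rng(config.seed)
    out = []
    for m in matrices:
        m = downsample(m, config, rng)
        out.append(asinh_transform(m, config.asinh_cofactor))
    return concatenate(out)


def read_cohort(events_dir, clinical_path=None):
    """Read a generated cohort directory back into EventMatrix objects
    (+ the clinical table when present)."""
    events_dir = Path(events_dir)
    paths = sorted(events_dir.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no event TSVs under {events_dir}")
    groups = {}
    if clinical_path is not None and Path(clinical_path).exists():
        clin = pd.read_csv(clinical_path, sep="\t")
        groups = dict(zip(clin["subject_id"], clin["group"]))
    else:
        clin = None
    matrices = [
        EventMatrix.from_tsv(p, group=groups.get(p.stem, "unknown")) for p in paths
    ]
    return (matrices, clin) if clin is not None else (matrices, None)
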