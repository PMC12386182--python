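"""Validated in-memory containers shared by all pipeline stages.

A *study* is a gene x sample matrix of raw read counts together with one
metadata record per sample (library).  Samples are grouped into
*conditions*: a condition is one unique combination of experiment,
tissue, light intensity, treatment duration and plant age, replicated
over one or more libraries.  Control libraries carry ``is_control=True``
and a ``duration_min`` that acts as a matched-time label (0 when the
experiment has a single common control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column/field is missing or has the wrong layout."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a model invariant."""


TISSUES = ("leaf", "seedling")

#: minutes per unit, for condition-id style duration encodings
_DURATION_UNITS = {
    "s": 1.0 / 60.0,
    "sec": 1.0 / 60.0,
    "second": 1.0 / 60.0,
    "seconds": 1.0 / 60.0,
    "min": 1.0,
    "minute": 1.0,
    "minutes": 1.0,
    "h": 60.0,
    "hour": 60.0,
    "hours": 60.0,
    "d": 1440.0,
    "day": 1440.0,
    "days": 1440.0,
}


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sequencing library."""

    sample_id: str
    experiment_id: str
    condition_id: str
    tissue: str
    intensity_ppfd: float
    duration_min: float
    age_days: float
    is_control: bool

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r} "
                f"(expected one of {TISSUES})"
            )
        if self.intensity_ppfd < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative intensity {self.intensity_ppfd}"
            )
        if self.duration_min < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative duration {self.duration_min}"
            )
        if self.age_days <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: non-positive age {self.age_days}"
            )


def parse_condition_id(condition_id: str) -> dict:
    """Parse a structured condition identifier.

    The convention is ``<experiment>_<TISSUE>_<age>_<intensity>_<value>_<unit>``,
    e.g. ``GSE132626_LEAF_15_500_1_hour`` -> experiment GSE132626, leaf
    tissue, 15-day-old plants, 500 umol m-2 s-1, 60 min.  Durations are
    normalised to minutes whatever unit the identifier uses.
    """
    parts = condition_id.split("_")
    if len(parts) < 6:
        raise SchemaError(
            f"condition_id {condition_id!r} does not match "
            "'<experiment>_<tissue>_<age>_<intensity>_<duration>_<unit>'"
        )
    unit = parts[-1].lower()
    if unit not in _DURATION_UNITS:
        raise SchemaError(
            f"condition_id {condition_id!r}: unknown duration unit {parts[-1]!r}"
        )
    value = float(parts[-2])
    intensity = float(parts[-3])
    age = float(parts[-4])
    tissue = parts[-5].lower()
    experiment = "_".join(parts[:-5])
    if tissue not in TISSUES:
        raise ValidationError(
            f"condition_id {condition_id!r}: unknown tissue {tissue!r}"
        )
    return {
        "experiment_id": experiment,
        "tissue": tissue,
        "age_days": age,
        "intensity_ppfd": intensity,
        "duration_min": value * _DURATION_UNITS[unit],
    }


@dataclass
class GeneAnnotation:
    """Functional annotation for one gene.

    ``tf_family`` is set exactly for genes treated as transcription
    factors; ``go_terms`` may be empty for unannotated genes.
    """

    gene_id: str
    description: str = ""
    tf_family: str | None = None
    go_terms: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_tf(self) -> bool:
        return self.tf_family is not None


@dataclass
class CountStudy:
    """Gene x sample raw count matrix with per-sample metadata.

    ``counts`` has one row per gene (ordered as ``genes``) and one column
    per sample (ordered as ``samples``); entries are non-negative
    integers.
    """

    genes: list[str]
    samples: list[SampleRecord]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate gene id {dup!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = np.mod(self.counts, 1)
            bad = np.argwhere((frac != 0) | ~np.isfinite(self.counts))
            if bad.size:
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count {self.counts[g, s]!r} at gene "
                    f"{self.genes[g]!r}, sample {self.samples[s].sample_id!r}"
                )
            self.counts = self.counts.astype(np.int64)
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            g, s = neg[0]
            raise ValidationError(
                f"negative count {self.counts[g, s]} at gene {self.genes[g]!r}, "
                f"sample {self.samples[s].sample_id!r}"
            )
        self._check_condition_consistency()

    def _check_condition_consistency(self) -> None:
        seen: dict[str, SampleRecord] = {}
        for s in self.samples:
            key = s.condition_id
            if key in seen:
                ref = seen[key]
                for f in ("experiment_id", "tissue", "intensity_ppfd", "duration_min"):
                    if getattr(s, f) != getattr(ref, f):
                        raise ValidationError(
                            f"condition {key!r}: samples {ref.sample_id!r} and "
                            f"{s.sample_id!r} disagree on {f}"
                        )
            else:
                seen[key] = s

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.samples]).set_index("sample_id")

    def experiments(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.experiment_id not in out:
                out.append(s.experiment_id)
        return out

    def conditions(self, stress_only: bool = False) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if stress_only and s.is_control:
                continue
            if s.condition_id not in out:
                out.append(s.condition_id)
        return out

    def condition_samples(self, condition_id: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.condition_id == condition_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountStudy":
        wanted = set(sample_ids)
        idx = [i for i, s in enumerate(self.samples) if s.sample_id in wanted]
        missing = wanted - {self.samples[i].sample_id for i in idx}
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)}")
        return CountStudy(
            genes=list(self.genes),
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx].copy(),
        )

    def subset_experiment(self, experiment_id: str) -> "CountStudy":
        ids = [s.sample_id for s in self.samples if s.experiment_id == experiment_id]
        if not ids:
            raise ValidationError(f"no samples for experiment {experiment_id!r}")
        return self.subset_samples(ids)

    def subset_genes(self, genes: Sequence[str]) -> "CountStudy":
        pos = {g: i for i, g in enumerate(self.genes)}
        try:
            idx = [pos[g] for g in genes]
        except KeyError as e:
            raise ValidationError(f"unknown gene id {e.args[0]!r}") from None
        return CountStudy(
            genes=list(genes),
            samples=list(self.samples),
            counts=self.counts[idx, :].copy(),
        )

    def drop_experiments(self, experiment_ids: Iterable[str]) -> "CountStudy":
        drop = set(experiment_ids)
        keep = [s.sample_id for s in self.samples if s.experiment_id not in drop]
        if not keep:
            raise ValidationError("excluding these experiments leaves no samples")
        return self.subset_samples(keep)
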