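"""Core containers for multi-omics data.

An :class:`OmicsView` holds one modality (gene expression, promoter
methylation, miRNA abundance, ...) as a features x samples real matrix with an
explicit missing-entry mask.  A :class:`MultiOmicsDataset` aligns several views
over a common sample universe (the union of per-view sample sets) together
with a right-censored survival table; samples absent from a view are flagged
in a samples x views presence mask rather than dropped, because the shared-
representation learner downstream can handle missing views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class OmicsDataError(ValueError):
    """Malformed or inconsistent -omics input."""


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    for i in ids:
        if i in seen:
            raise OmicsDataError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OmicsView:
    """One -omics modality: a features x samples matrix plus missing mask."""

    name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise OmicsDataError("values must be a 2-D matrix (features x samples)")
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise OmicsDataError(
                f"view {self.name!r}: matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        nonfinite = ~np.isfinite(self.values)
        if self.missing_mask is None:
            self.missing_mask = nonfinite
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise OmicsDataError("missing_mask shape must match values")
            # invariant: every non-finite cell is masked
            self.missing_mask = self.missing_mask | nonfinite

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.feature_ids, columns=self.sample_ids)

    def subset(self, features=None, samples=None) -> "OmicsView":
        """Return a copy restricted to the given feature/sample ids (in the given order)."""
        fidx = (
            np.arange(self.n_features)
            if features is None
            else np.array([self.feature_ids.index(f) for f in features], dtype=int)
        )
        sidx = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self.sample_ids.index(s) for s in samples], dtype=int)
        )
        return OmicsView(
            name=self.name,
            feature_ids=[self.feature_ids[i] for i in fidx],
            sample_ids=[self.sample_ids[i] for i in sidx],
            values=self.values[np.ix_(fidx, sidx)],
            missing_mask=self.missing_mask[np.ix_(fidx, sidx)],
        )


@dataclass
class SurvivalTable:
    """Right-censored follow-up: per-sample time on study and event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    unit: str = "days"  # recorded, never converted

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise OmicsDataError("survival time/event length must match sample_ids")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise OmicsDataError("all survival times must be positive and finite")
        if not np.all(np.isin(self.event, [0, 1])):
            raise OmicsDataError("event indicator must be 0 (censored) or 1 (event)")

    def subset(self, samples) -> "SurvivalTable":
        idx = np.array([self.sample_ids.index(s) for s in samples])
        return SurvivalTable(list(samples), self.time[idx], self.event[idx], self.unit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass
class MultiOmicsDataset:
    """Views aligned on the union of their sample sets, plus survival.

    Each view's matrix is re-indexed to the full sample universe; columns for
    samples the view never measured hold NaN and are marked absent in
    ``presence`` (samples x views).  Every sample is present in at least one
    view and has a survival record.
    """

    views: list[OmicsView]
    presence: np.ndarray
    survival: SurvivalTable
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            self.sample_ids = list(self.views[0].sample_ids)
        self.presence = np.asarray(self.presence, dtype=bool)
        n, v = len(self.sample_ids), len(self.views)
        if self.presence.shape != (n, v):
            raise OmicsDataError(f"presence must be {n} samples x {v} views")
        if not np.all(self.presence.any(axis=1)):
            bad = [self.sample_ids[i] for i in np.where(~self.presence.any(axis=1))[0]]
            raise OmicsDataError(f"samples present in no view: {bad}")
        for view in self.views:
            if view.sample_ids != self.sample_ids:
                raise OmicsDataError(
                    f"view {view.name!r} is not aligned to the dataset sample universe"
                )
        if self.survival.sample_ids != self.sample_ids:
            raise OmicsDataError("survival table is not aligned to the sample universe")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    def view(self, name: str) -> OmicsView:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass
class PromoterAnnotation:
    """probe id -> (gene id, promoter region), one entry per probe."""

    mapping: dict[str, tuple[str, str]]

    VALID_REGIONS = ("TSS200", "TSS1500")

    def __post_init__(self) -> None:
        for probe, (gene, region) in self.mapping.items():
            if region not in self.VALID_REGIONS:
                raise OmicsDataError(
                    f"probe {probe!r}: region {region!r} not in {self.VALID_REGIONS}"
                )

    def genes_for(self, probes) -> dict[str, list[str]]:
        """Group annotated probes (preserving input order) by gene."""
        out: dict[str, list[str]] = {}
        for p in probes:
            if p in self.mapping:
                out.setdefault(self.mapping[p][0], []).append(p)
        return out


# ---------------------------------------------------------------------------
# readers / writers (TSV; gzip transparent via pandas/compression inference)
# ---------------------------------------------------------------------------


def read_omics_view(path, name: str) -> OmicsView:
    """Read a features x samples TSV matrix (first column = feature ids).

    Empty cells, 'NA' and non-finite numbers become masked missing entries.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""],
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message path
        raise OmicsDataError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise OmicsDataError(f"{path}: duplicated feature id(s): {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise OmicsDataError(f"{path}: duplicated sample id(s): {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise OmicsDataError(f"{path}: non-numeric cell: {exc}") from exc
    return OmicsView(
        name=name,
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
    )


def write_omics_view(view: OmicsView, path) -> None:
    # %.17g guarantees doubles survive the text round-trip bit-exactly
    view.to_frame().to_csv(path, sep="\t", index_label="feature_id",
                           float_format="%.17g")


def read_survival(path, unit: str = "days") -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise OmicsDataError(f"{path}: survival table needs columns {sorted(required)}")
    return SurvivalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
        unit=unit,
    )


def write_survival(surv: SurvivalTable, path) -> None:
    surv.to_frame().to_csv(path, sep="\t", index=False)


def read_promoter_annotation(path) -> PromoterAnnotation:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "gene_id", "region"}
    if not required.issubset(df.columns):
        raise OmicsDataError(f"{path}: annotation needs columns {sorted(required)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise OmicsDataError(f"{path}: probe(s) annotated more than once: {dup}")
    mapping = {
        str(r.probe_id): (str(r.gene_id), str(r.region)) for r in df.itertuples()
    }
    return PromoterAnnotation(mapping)
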