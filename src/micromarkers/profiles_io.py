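"""Reading, validating, filtering and writing abundance tables and metadata.

Profiles are sample-by-feature relative-abundance matrices (compositional:
each sample row sums to 1).  Tables are plain TSV with one header row of
IDs and one ID column; metadata TSVs carry a binary disease label and
numeric clinical covariates (fbg, bmi, age, weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9

#: covariates recognised in metadata files (extra columns are ignored, logged)
KNOWN_COVARIATES = ("fbg", "bmi", "age", "weight")


@dataclass
class AbundanceProfile:
    """Sample x feature relative-abundance matrix.

    values[i, j] is the relative abundance of feature j in sample i;
    all values are finite and >= 0, IDs are unique, and after
    :func:`renormalize` every row sums to 1 within 1e-9.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} id: {dupes[0]!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("abundance values must be finite")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def subset_features(self, feature_ids: list[str]) -> "AbundanceProfile":
        """Column subset in the given order; unknown features are an error."""
        idx = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"unknown feature id: {missing[0]!r}")
        cols = [idx[f] for f in feature_ids]
        return AbundanceProfile(list(self.sample_ids), list(feature_ids),
                                self.values[:, cols].copy())

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceProfile":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample id: {missing[0]!r}")
        rows = [idx[s] for s in sample_ids]
        return AbundanceProfile(list(sample_ids), list(self.feature_ids),
                                self.values[rows].copy())


@dataclass
class SampleMetadata:
    """Per-sample disease label and numeric covariates.

    label: 1 = case, 0 = control.  Covariate units: fbg mmol/L,
    bmi kg/m^2, age years, weight kg.  Missing covariates are allowed
    (stored as NaN); a missing label is not.
    """

    sample_id: str
    label: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(
                f"label for sample {self.sample_id!r} must be 0 or 1, "
                f"got {self.label!r}")
        for k, v in self.covariates.items():
            if v is not None and not np.isnan(v) and not np.isfinite(v):
                raise ValueError(
                    f"covariate {k!r} of sample {self.sample_id!r} not finite")


def _detect_scale(values: np.ndarray) -> float:
    """Auto-detect fraction vs percentage scale from row-sum magnitude."""
    median_sum = float(np.median(values.sum(axis=1)))
    if median_sum > 10.0:
        logger.info("row sums ~%.3g: interpreting values as percentages", median_sum)
        return 100.0
    return 1.0


def read_abundance_table(path, orientation: str = "samples_as_rows",
                         renormalize_rows: bool = True) -> AbundanceProfile:
    """Read a TSV abundance table into the canonical samples-as-rows form.

    Parameters
    ----------
    path : file path
        TSV with one header row of IDs and one leading ID column.
    orientation : {"samples_as_rows", "features_as_rows"}
        Layout of the file; ``features_as_rows`` tables are transposed.
    renormalize_rows : bool
        Close each sample row to sum 1 (default).  Values in percentage
        scale ([0, 100]) are auto-detected and stored as fractions.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in header:   # pandas silently mangles duplicate columns
        if name in seen:
            raise ValueError(f"duplicate id in header: {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "features_as_rows":
        df = df.T
    try:
        body = df.astype(float)
    except ValueError:
        for i, row in df.iterrows():
            for j, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {i!r}, column {j!r}: {cell!r}"
                    ) from None
        raise
    values = body.to_numpy()
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(f"negative value at row {body.index[i]!r}, "
                         f"column {body.columns[j]!r}")
    values = values / _detect_scale(values)
    profile = AbundanceProfile([str(s) for s in body.index],
                               [str(f) for f in body.columns], values)
    return renormalize(profile) if renormalize_rows else profile


def write_abundance_table(profile: AbundanceProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", float_format="%.12g",
                              index_label="sample_id")


def renormalize(profile: AbundanceProfile) -> AbundanceProfile:
    """Close each sample row to sum 1.  All-zero rows are an error."""
    sums = profile.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"sample {profile.sample_ids[zero[0]]!r} is all-zero; "
                         "cannot renormalize")
    return AbundanceProfile(list(profile.sample_ids), list(profile.feature_ids),
                            profile.values / sums[:, None])


def filter_min_prevalence(profile: AbundanceProfile,
                          min_samples: int) -> AbundanceProfile:
    """Drop features nonzero in fewer than ``min_samples`` samples.

    Feature order is preserved among survivors; an empty result is an
    error.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (profile.values > 0).sum(axis=0)
    keep = prevalence >= min_samples
    if not keep.any():
        raise ValueError(f"no feature present in >= {min_samples} samples")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("prevalence filter dropped %d of %d features",
                    n_dropped, profile.n_features)
    kept_ids = [f for f, k in zip(profile.feature_ids, keep) if k]
    return AbundanceProfile(list(profile.sample_ids), kept_ids,
                            profile.values[:, keep].copy())


def read_metadata_table(path) -> list[SampleMetadata]:
    """Read a metadata TSV with columns sample_id, label and covariates.

    Recognised covariate columns: fbg, bmi, age, weight (missing values
    allowed).  Extra columns are ignored with a log message.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sample_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing column(s): {sorted(missing)}")
    extra = set(df.columns) - required - set(KNOWN_COVARIATES)
    if extra:
        logger.info("ignoring extra metadata columns: %s", sorted(extra))
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    records = []
    for _, row in df.iterrows():
        cov = {c: float(row[c]) for c in KNOWN_COVARIATES if c in df.columns}
        records.append(SampleMetadata(sample_id=str(row["sample_id"]),
                                      label=int(row["label"]), covariates=cov))
    return records


def write_metadata_table(metadata: list[SampleMetadata], path) -> None:
    cov_names = sorted({k for m in metadata for k in m.covariates})
    rows = [{"sample_id": m.sample_id, "label": m.label,
             **{c: m.covariates.get(c, float("nan")) for c in cov_names}}
            for m in metadata]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class PairedDataset:
    """An abundance profile inner-joined with its metadata.

    Samples appear in profile order; ``labels`` and ``covariates`` rows
    are aligned to ``profile.sample_ids``.
    """

    profile: AbundanceProfile
    metadata: list[SampleMetadata]

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.label for m in self.metadata], dtype=int)

    def covariate(self, name: str) -> np.ndarray:
        return np.array([m.covariates.get(name, float("nan"))
                         for m in self.metadata], dtype=float)


def align(profile: AbundanceProfile,
          metadata: list[SampleMetadata]) -> PairedDataset:
    """Inner-join profile and metadata on sample id, in profile order."""
    by_id = {m.sample_id: m for m in metadata}
    shared = [s for s in profile.sample_ids if s in by_id]
    if not shared:
        raise ValueError("no sample ids shared between profile and metadata")
    dropped_profile = [s for s in profile.sample_ids if s not in by_id]
    dropped_meta = [s for s in by_id if s not in set(profile.sample_ids)]
    if dropped_profile:
        logger.info("align: dropped %d profile sample(s) without metadata: %s",
                    len(dropped_profile), dropped_profile[:10])
    if dropped_meta:
        logger.info("align: dropped %d metadata sample(s) without profile: %s",
                    len(dropped_meta), dropped_meta[:10])
    return PairedDataset(profile=profile.subset_samples(shared),
                         metadata=[by_id[s] for s in shared])
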