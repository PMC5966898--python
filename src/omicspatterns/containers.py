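"""Core in-memory containers shared across the pipeline.

The pipeline operates on feature-by-sample matrices (log2 expression or
methylation beta fractions) with per-sample design metadata describing a
two-arm passaging time course: a parental line at generation 0 and
treated/control arms at generations 1..G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARMS = ("treated", "control", "parental")

#: Required columns of a sample-metadata table (indexed by sample_id).
SAMPLE_META_COLUMNS = ("arm", "generation", "replicate")


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table: arms, generations, parental<->gen0."""
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns {missing}")
    if meta.index.duplicated().any():
        dups = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    bad_arm = sorted(set(meta["arm"]) - set(ARMS))
    if bad_arm:
        raise ValueError(f"unknown arm values {bad_arm}; expected {ARMS}")
    gen = meta["generation"].astype(int)
    if (gen < 0).any():
        raise ValueError("generations must be >= 0")
    parental = meta["arm"] == "parental"
    if not (parental == (gen == 0)).all():
        raise ValueError("parental samples must be exactly the generation-0 samples")
    out = meta.copy()
    out["generation"] = gen
    return out


@dataclass
class OmicsMatrix:
    """Feature-by-sample value matrix with per-sample design metadata.

    ``values`` holds log2 expression (>= 0) or methylation beta fractions in
    [0, 1]. For methylation, optional methylated/unmethylated intensity
    channels ``M``/``U`` may accompany the betas, in which case
    ``values == M / (M + U)`` entrywise (NaN where M + U == 0).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    platform: str  # "expression" | "methylation"
    M: pd.DataFrame | None = None
    U: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.platform not in ("expression", "methylation"):
            raise ValueError(f"unknown platform {self.platform!r}")
        self.samples = validate_sample_meta(self.samples)
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("value columns do not match sample metadata index")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:10]}")
        vals = self.values.to_numpy(float)
        if self.platform == "methylation":
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("methylation beta values must lie in [0, 1]")
        for chan in (self.M, self.U):
            if chan is not None:
                if chan.shape != self.values.shape:
                    raise ValueError("intensity channel shape mismatch")
                if (chan.to_numpy(float) < 0).any():
                    raise ValueError("intensity channels must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features) -> "OmicsMatrix":
        features = [f for f in features if f in self.values.index]
        return OmicsMatrix(
            values=self.values.loc[features],
            samples=self.samples,
            platform=self.platform,
            M=None if self.M is None else self.M.loc[features],
            U=None if self.U is None else self.U.loc[features],
        )


@dataclass
class UncertaintyMatrix:
    """Per-entry standard deviation matching an :class:`OmicsMatrix`."""

    sigma: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.sigma.to_numpy(float)
        if np.isfinite(s).any() and np.nanmin(s[np.isfinite(s)]) < 0:
            raise ValueError("uncertainties must be non-negative")

    def matches(self, omics: OmicsMatrix) -> bool:
        return self.sigma.shape == omics.values.shape


#: Required columns of a probe-annotation table.
ANNOTATION_COLUMNS = ("probe_id", "gene", "chrom", "tss_distance", "cpg_island", "snp")

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"probe annotation missing columns {missing}")
    if (ann["tss_distance"].astype(float) < 0).any():
        raise ValueError("tss_distance must be >= 0 (distances are magnitudes)")
    if ann["probe_id"].duplicated().any():
        dups = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids in annotation: {dups[:10]}")
    out = ann.copy()
    out["cpg_island"] = out["cpg_island"].astype(bool)
    out["snp"] = out["snp"].astype(bool)
    return out


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): name -> (description, genes)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()
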