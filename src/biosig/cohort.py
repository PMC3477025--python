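"""Synthetic multi-modality cohort generation with known discriminative support.

Emulates the statistical structure of a baseline clinical feature table for
MCI conversion prediction: two diagnostic groups (non-converters labelled -1,
converters labelled +1), mixed modalities (cognitive scores, a large block of
correlated MRI-derived measures, demographics, an ordinal APOE allele count,
lab tests, and a CSF panel available only on a subject subset), with a sparse
set of planted discriminative features whose standardized group mean
differences are chosen to match the effect sizes seen in real cohorts.

Continuous features are drawn per group from a multivariate Gaussian with
exchangeable (compound-symmetric) within-modality correlation rho and unit
marginal variance, so a planted feature with effect size ``d`` has its group
means separated by ``d`` standard deviations.  The APOE-like feature is a
3-category multinomial (allele count 0/1/2) with class-dependent
probabilities.  Missingness is missing-completely-at-random at the subject
level: a subject either has the whole modality or none of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModalitySpec",
    "CohortSpec",
    "GroundTruth",
    "FeatureTable",
    "generate_cohort",
    "default_cohort_spec",
    "read_cohort",
    "write_cohort",
    "write_ground_truth",
    "read_ground_truth",
]

MODALITY_NAMES = ("cognitive", "mri", "demographic", "apoe", "lab", "csf")


@dataclass(frozen=True)
class ModalitySpec:
    """One block of features sharing a modality tag.

    Parameters
    ----------
    name:
        Modality tag, one of ``cognitive | mri | demographic | apoe | lab | csf``.
    n_features:
        Number of features in the block (must be 1 for a categorical block).
    planted:
        ``(local index, standardized effect size d)`` pairs; the group mean of
        a planted feature is shifted by ``d`` (converters minus
        non-converters) on the unit-variance scale.
    block_correlation:
        Exchangeable correlation rho in [0, 1) among the block's features.
    availability:
        Fraction of subjects with non-missing values; below 1 the modality is
        missing all-or-none per subject, completely at random.
    categorical:
        If true the block is a single 3-category allele count drawn from
        ``category_probs`` per group.
    category_probs:
        ``{-1: (p0, p1, p2), +1: (p0, p1, p2)}`` category probabilities.
    feature_names:
        Optional explicit names; autogenerated as ``<name>_<i>`` otherwise.
    """

    name: str
    n_features: int
    planted: tuple[tuple[int, float], ...] = ()
    block_correlation: float = 0.0
    availability: float = 1.0
    categorical: bool = False
    category_probs: dict[int, tuple[float, float, float]] | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in MODALITY_NAMES:
            raise ValueError(f"unknown modality name {self.name!r}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must lie in [0, 1)")
        if not (0.0 < self.availability <= 1.0):
            raise ValueError("availability must lie in (0, 1]")
        for j, _ in self.planted:
            if not (0 <= j < self.n_features):
                raise ValueError(f"planted index {j} out of range")
        if len({j for j, _ in self.planted}) != len(self.planted):
            raise ValueError("duplicate planted indices")
        if self.categorical:
            if self.n_features != 1:
                raise ValueError("categorical modality must have one feature")
            if self.category_probs is None:
                raise ValueError("categorical modality needs category_probs")
            for g, probs in self.category_probs.items():
                if g not in (-1, 1):
                    raise ValueError("category_probs keyed by group label -1/+1")
                if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                    raise ValueError("category probabilities must sum to 1")
        if self.feature_names is not None and len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length mismatch")

    def names(self) -> list[str]:
        if self.feature_names is not None:
            return list(self.feature_names)
        if self.n_features == 1:
            return [self.name]
        return [f"{self.name}_{i:03d}" for i in range(self.n_features)]


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters: group sizes, modality blocks, and a seed."""

    n_nonconverter: int = 177
    n_converter: int = 142
    modalities: tuple[ModalitySpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonconverter < 2 or self.n_converter < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not self.modalities:
            raise ValueError("at least one modality required")
        names = [n for m in self.modalities for n in m.names()]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names across modalities")

    @property
    def n_subjects(self) -> int:
        return self.n_nonconverter + self.n_converter

    @property
    def n_features(self) -> int:
        return sum(m.n_features for m in self.modalities)


@dataclass(frozen=True)
class GroundTruth:
    """The planted discriminative support, by global feature name."""

    support: frozenset[str]
    effect_sizes: dict[str, float]
    seed: int


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels in {-1, +1} and modality tags."""

    subject_ids: list[str]
    labels: np.ndarray
    X: np.ndarray
    feature_names: list[str]
    modality_tags: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject ids / labels do not match matrix rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if len(self.feature_names) != p or len(self.modality_tags) != p:
            raise ValueError("feature names / tags do not match matrix columns")
        if not set(np.unique(self.labels)) == {-1, 1}:
            raise ValueError("labels must contain both classes, coded -1/+1")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.feature_names.index(n) for n in names]
        return self.X[:, idx]

    def modality_features(self, *tags: str) -> list[str]:
        """Feature names belonging to any of the given modality tags."""
        want = set(tags)
        return [n for n, t in zip(self.feature_names, self.modality_tags) if t in want]

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            labels=self.labels.copy(),
            X=self.X[:, idx].copy(),
            feature_names=[self.feature_names[i] for i in idx],
            modality_tags=[self.modality_tags[i] for i in idx],
        )

    def complete_cases(self, names: Sequence[str] | None = None) -> "FeatureTable":
        """Drop subjects with any missing value among the given features."""
        checked = self.X if names is None else self.columns(list(names))
        keep = ~np.isnan(checked).any(axis=1)
        return FeatureTable(
            subject_ids=[s for s, k in zip(self.subject_ids, keep) if k],
            labels=self.labels[keep],
            X=self.X[keep],
            feature_names=list(self.feature_names),
            modality_tags=list(self.modality_tags),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _exchangeable_mvn(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """Draw n samples from N(0, (1-rho) I + rho 11^T), unit marginal variance.

    The compound-symmetric factor z*sqrt(rho) + e*sqrt(1-rho) with a shared
    scalar z per sample avoids forming the p x p Cholesky factor.
    """
    if rho == 0.0:
        return rng.standard_normal((n, p))
    shared = rng.standard_normal((n, 1))
    indiv = rng.standard_normal((n, p))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table and its ground-truth support from a spec.

    Deterministic: identical spec (including seed) yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_nonconverter, spec.n_converter
    n = n0 + n1
    labels = np.concatenate([-np.ones(n0, dtype=int), np.ones(n1, dtype=int)])

    blocks: list[np.ndarray] = []
    names: list[str] = []
    tags: list[str] = []
    support: set[str] = set()
    effects: dict[str, float] = {}

    for mod in spec.modalities:
        mnames = mod.names()
        if mod.categorical:
            probs = mod.category_probs
            col = np.empty(n)
            col[:n0] = rng.choice(3, size=n0, p=probs[-1])
            col[n0:] = rng.choice(3, size=n1, p=probs[1])
            block = col[:, None]
            # marginal standardized difference of the allele count
            m0 = sum(k * probs[-1][k] for k in range(3))
            m1 = sum(k * probs[1][k] for k in range(3))
            v0 = sum(k * k * probs[-1][k] for k in range(3)) - m0**2
            v1 = sum(k * k * probs[1][k] for k in range(3)) - m1**2
            d = (m1 - m0) / np.sqrt((v0 + v1) / 2.0)
            if abs(d) > 1e-12:
                support.add(mnames[0])
                effects[mnames[0]] = float(d)
        else:
            block = _exchangeable_mvn(rng, n, mod.n_features, mod.block_correlation)
            for j, d in mod.planted:
                block[n0:, j] += d
                if d != 0.0:
                    support.add(mnames[j])
                    effects[mnames[j]] = float(d)
        if mod.availability < 1.0:
            n_avail = int(round(mod.availability * n))
            if n_avail == 0:
                raise ValueError("availability leaves no subject with data")
            missing = rng.choice(n, size=n - n_avail, replace=False)
            block[missing, :] = np.nan
        blocks.append(block)
        names.extend(mnames)
        tags.extend([mod.name] * mod.n_features)

    X = np.hstack(blocks)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    table = FeatureTable(subject_ids, labels, X, names, tags)
    truth = GroundTruth(frozenset(support), effects, spec.seed)
    return table, truth


# ---------------------------------------------------------------------------
# Default cohort emulating the published baseline table
# ---------------------------------------------------------------------------

_COGNITIVE_NAMES = (
    "MMSE", "CDR_SB", "ADAS_total11", "ADAS_total13",
    "ADAS_Q1", "ADAS_Q2", "ADAS_Q3", "ADAS_Q4", "ADAS_Q5", "ADAS_Q6",
    "ADAS_Q7", "ADAS_Q8", "ADAS_Q9", "ADAS_Q10", "ADAS_Q11", "ADAS_Q12",
    "ADAS_Q14", "FAQ", "LDEL", "LIMM", "TRAA", "TRAB",
)

# Standardized converter-minus-nonconverter differences computed from the
# published group summaries (mean difference over pooled SD); memory-loaded
# cognitive scores and medial-temporal volumes carry the signal, everything
# else is null.
_COGNITIVE_EFFECTS = {
    "ADAS_total13": 0.83,
    "ADAS_Q4": 0.81,       # delayed word recall
    "ADAS_Q1": 0.77,       # word recall
    "ADAS_total11": 0.75,
    "FAQ": 0.72,           # activities of daily living
    "LDEL": -0.71,         # logical memory delayed: lower in converters
    "ADAS_Q7": 0.60,       # orientation
    "CDR_SB": 0.55,
}

_MRI_PLANTED = {
    "mri_L_hippocampus_vol": -0.65,
    "mri_L_entorhinal_vol": -0.60,
    "mri_L_amygdala_vol": -0.55,
    "mri_R_inf_parietal_vol": -0.50,
    "mri_L_isthmus_cingulate_thk": -0.45,
    "mri_L_cuneus_vol": -0.40,
}

# Allele-count proportions per group from the published 103/59/15 and
# 48/71/23 counts.
_APOE_PROBS = {
    -1: (103 / 177, 59 / 177, 15 / 177),
    1: (48 / 142, 71 / 142, 23 / 142),
}

_CSF_NAMES = ("csf_t_tau", "csf_abeta42", "csf_p_tau",
              "csf_t_tau_abeta42", "csf_p_tau_abeta42")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default two-group cohort: 177 non-converters, 142 converters,
    285 features across six modalities, 15 planted discriminative features.

    Cognitive block (22 features, rho=0.2): 8 planted with |d| in
    [0.55, 0.83] from the published group summaries.  MRI-like block
    (237 features, exchangeable rho=0.5): 6 planted volumes/thicknesses with
    |d| in [0.40, 0.65], negative because atrophy lowers converters' values.
    APOE allele count with the published class-dependent proportions
    (marginal d ~ 0.6).  Age, education, 18 lab tests and the 5-feature CSF
    panel are null; CSF is observed for ~50% of subjects, all-or-none.
    """
    mri_names = [f"mri_{i:03d}" for i in range(237 - len(_MRI_PLANTED))]
    mri_names = list(_MRI_PLANTED) + mri_names
    mri_planted = tuple((i, d) for i, d in enumerate(_MRI_PLANTED.values()))
    cog_planted = tuple(
        (_COGNITIVE_NAMES.index(k), v) for k, v in _COGNITIVE_EFFECTS.items()
    )
    return CohortSpec(
        n_nonconverter=177,
        n_converter=142,
        seed=seed,
        modalities=(
            ModalitySpec("cognitive", len(_COGNITIVE_NAMES), planted=cog_planted,
                         block_correlation=0.2, feature_names=_COGNITIVE_NAMES),
            ModalitySpec("mri", 237, planted=mri_planted, block_correlation=0.5,
                         feature_names=tuple(mri_names)),
            ModalitySpec("demographic", 2, feature_names=("age", "education")),
            ModalitySpec("apoe", 1, categorical=True, category_probs=_APOE_PROBS,
                         feature_names=("APOE_alleles",)),
            ModalitySpec("lab", 18,
                         feature_names=tuple(f"lab_RCT{i:02d}" for i in range(18))),
            ModalitySpec("csf", len(_CSF_NAMES), availability=160 / 319,
                         feature_names=_CSF_NAMES),
        ),
    )


# ---------------------------------------------------------------------------
# CSV / JSON round-trip
# ---------------------------------------------------------------------------

def write_cohort(table: FeatureTable, path: str | Path) -> None:
    """Write a cohort CSV: header ``subject_id,label,<features>``; a second
    header line ``#modality,,<tags>`` keeps the modality tags; missing values
    are empty cells."""
    path = Path(path)
    df = table.to_frame()
    with open(path, "w") as fh:
        fh.write(",".join(["subject_id", "label"] + table.feature_names) + "\n")
        fh.write(",".join(["#modality", ""] + table.modality_tags) + "\n")
        df.to_csv(fh, index=False, header=False, float_format="%.10g")


def read_cohort(path: str | Path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        second = fh.readline().rstrip("\n").split(",")
        if header[:2] != ["subject_id", "label"]:
            raise ValueError("cohort CSV must start with subject_id,label columns")
        if len(set(header[2:])) != len(header[2:]):
            raise ValueError("duplicate feature names in header")
        if second and second[0] == "#modality":
            tags = second[2:]
            body = fh
            df = pd.read_csv(body, header=None, names=header)
        else:
            raise ValueError("cohort CSV missing the #modality tag line")
    if len(tags) != len(header) - 2:
        raise ValueError("modality tag line does not match header")
    labels = df["label"].to_numpy()
    uniq = set(np.unique(labels[~pd.isna(labels)]))
    if not uniq == {-1, 1}:
        raise ValueError("label column must contain both classes coded -1/+1")
    return FeatureTable(
        subject_ids=[str(s) for s in df["subject_id"]],
        labels=labels.astype(int),
        X=df[header[2:]].to_numpy(dtype=float),
        feature_names=header[2:],
        modality_tags=tags,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "support": sorted(truth.support),
        "effect_sizes": {k: truth.effect_sizes[k] for k in sorted(truth.effect_sizes)},
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(frozenset(payload["support"]),
                       dict(payload["effect_sizes"]), int(payload["seed"]))
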