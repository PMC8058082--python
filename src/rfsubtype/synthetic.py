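"""Synthetic cohorts with planted severity subtypes.

The generator emulates the statistical structure the downstream analysis
assumes: a discovery and a validation sample of cases and healthy controls
(HC); ordinal clinical-scale items driven by a single latent severity
factor, with cases split into planted subtypes that differ in mean latent
severity; a multi-omic biomarker panel in which a minority of markers carry
graded group-dependent mean shifts (mostly down-regulated with increasing
severity, with a small up-regulated minority such as a lactate-like
metabolite) on top of equicorrelated within-subclass noise; and five
auxiliary feature classes with weaker, class-specific signal.

Clinical items follow a graded-response structure: item j has a
discrimination (loading) b_j and a difficulty d_j, and a subject with
latent severity z scores ``clip(round(b_j * (z - d_j) + noise), 0, max)``
on the item's native ordinal range. Difficulties are bimodal, as on real
symptom inventories: "easy" items that any case endorses (and on which
severe cases saturate near the scale ceiling) and "hard" items that only
the severe subtype endorses. The hard items of the non-severity scales sit
inside the latent gap between the two planted subtypes; they are what
gives a case-vs-control forest terminal-node structure that separates the
subtypes. The severity scale's own hard items sit in the severe tail so
that its group totals land near the clinical ranges of a
moderate-vs-severe cohort (HC near the floor, subtype means roughly 54 and
76 on a 0-136 total).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_CLINICAL_ITEM = "clinical_item"
CLASS_CLINICAL_SUMMARY = "clinical_summary"
CLASS_BIOMARKER = "biomarker"

#: auxiliary feature classes considered for subtype classification
AUX_CLASSES = (
    "comorbidity",
    "neurocognitive",
    "demographic",
    "psychiatric_history",
    "premilitary_trauma",
)

KNOWN_CLASSES = frozenset((CLASS_CLINICAL_ITEM, CLASS_CLINICAL_SUMMARY, CLASS_BIOMARKER) + AUX_CLASSES)

#: biomarker subclasses and default panel sizes (342 markers in total)
DEFAULT_BIOMARKER_CLASSES = {
    "methylation": 140,
    "mirna": 60,
    "metabolite": 60,
    "protein": 40,
    "endocrine": 15,
    "clinical_lab": 15,
    "physiological": 12,
}

DEFAULT_AUX_SIZES = {
    "comorbidity": 8,
    "neurocognitive": 10,
    "demographic": 6,
    "psychiatric_history": 6,
    "premilitary_trauma": 6,
}

#: severity-decreasing auxiliary classes (informative features shift down)
AUX_DOWN = frozenset({"neurocognitive"})

SEVERITY_SCALE_ID = "CAPS"


def _default_items_per_scale() -> tuple[int, ...]:
    # scale 1 is the 17-item, 0-8 severity scale (CAPS analog); the other
    # fifteen are 10-item 0-4 self-report scales
    return (17,) + (10,) * 15


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``severity_means`` holds the latent severity mean of HC followed by one
    entry per planted case subtype, and must be strictly increasing.
    ``marker_effect_size`` is the standardized mean difference (Cohen's d)
    between HC and the most severe subtype for an informative biomarker;
    milder subtypes receive proportionally graded shifts.
    """

    n_hc_discovery: int = 71
    n_case_discovery: int = 74
    n_hc_validation: int = 36
    n_case_validation: int = 26
    subtype_proportions: tuple[float, ...] = (0.35, 0.65)
    severity_means: tuple[float, ...] = (-0.6, 1.45, 3.6)
    severity_sd: float = 0.10
    n_clinical_scales: int = 16
    items_per_scale: tuple[int, ...] = field(default_factory=_default_items_per_scale)
    item_loading_range: tuple[float, float] = (0.7, 1.3)
    item_loading: float = 4.6
    hard_item_loading: float = 2.4
    hard_item_fraction: float = 0.5
    easy_difficulty_range: tuple[float, float] = (-0.5, 0.8)
    gap_difficulty_range: tuple[float, float] = (2.3, 3.4)
    tail_difficulty_range: tuple[float, float] = (3.4, 4.5)
    item_noise_sd: float = 0.8
    n_biomarkers_per_class: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKER_CLASSES))
    n_informative_markers: int = 40
    marker_effect_size: float = 1.0
    marker_up_fraction: float = 0.1
    block_correlation: float = 0.3
    aux_class_effect_sizes: dict = field(
        default_factory=lambda: {
            "comorbidity": 0.3,
            "neurocognitive": 0.5,
            "demographic": 0.1,
            "psychiatric_history": 0.8,
            "premilitary_trauma": 0.3,
        }
    )
    seed: int = 0

    def n_subtypes(self) -> int:
        return len(self.subtype_proportions)

    def validate(self) -> None:
        counts = (self.n_hc_discovery, self.n_case_discovery, self.n_hc_validation, self.n_case_validation)
        if any(c < 0 for c in counts):
            raise ValueError("subject counts must be non-negative")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        if len(self.severity_means) != self.n_subtypes() + 1:
            raise ValueError("severity_means must have one entry for HC plus one per subtype")
        if any(b <= a for a, b in zip(self.severity_means, self.severity_means[1:])):
            raise ValueError("severity_means must be strictly increasing (HC < S1 < ... )")
        if self.severity_sd <= 0:
            raise ValueError("severity_sd must be positive")
        if self.marker_effect_size < 0:
            raise ValueError("marker_effect_size must be non-negative")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must lie in [0, 1)")
        if len(self.items_per_scale) != self.n_clinical_scales:
            raise ValueError("items_per_scale must have n_clinical_scales entries")
        unknown = set(self.aux_class_effect_sizes) - set(AUX_CLASSES)
        if unknown:
            raise ValueError(f"unknown auxiliary classes: {sorted(unknown)}")


@dataclass
class CohortTable:
    """Subject-by-feature matrix with feature metadata and subject labels.

    ``values`` is a subjects x features DataFrame (index: subject_id).
    ``subjects`` has columns group ('case'/'hc'), role
    ('discovery'/'validation') and true_subtype ('' for HC; generator ground
    truth for cases). ``features`` has columns class, subclass, scale_id and
    expected_direction, indexed by feature_id in column order of ``values``.
    """

    values: pd.DataFrame
    subjects: pd.DataFrame
    features: pd.DataFrame

    def validate(self) -> None:
        if not self.values.index.equals(self.subjects.index):
            raise ValueError("values rows and subjects table disagree")
        if list(self.values.columns) != list(self.features.index):
            raise ValueError("values columns and feature metadata disagree")
        unknown = set(self.features["class"]) - KNOWN_CLASSES
        if unknown:
            bad = self.features.index[self.features["class"].isin(unknown)][0]
            raise ValueError(f"unknown feature class for feature {bad!r}")
        if self.values.isna().any().any():
            raise ValueError("cohort values contain missing entries")
        has_subtype = self.subjects["true_subtype"] != ""
        if (has_subtype & (self.subjects["group"] != "case")).any():
            raise ValueError("true_subtype defined for a non-case subject")

    def feature_ids(self, feature_class: str | None = None, subclass: str | None = None) -> list[str]:
        meta = self.features
        mask = np.ones(len(meta), dtype=bool)
        if feature_class is not None:
            mask &= (meta["class"] == feature_class).to_numpy()
        if subclass is not None:
            mask &= (meta["subclass"] == subclass).to_numpy()
        return list(meta.index[mask])

    def subset(self, role: str | None = None, group: str | None = None) -> "CohortTable":
        mask = np.ones(len(self.subjects), dtype=bool)
        if role is not None:
            mask &= (self.subjects["role"] == role).to_numpy()
        if group is not None:
            mask &= (self.subjects["group"] == group).to_numpy()
        return CohortTable(self.values.loc[mask], self.subjects.loc[mask], self.features)

    @property
    def severity_total_id(self) -> str:
        meta = self.features
        ids = meta.index[(meta["class"] == CLASS_CLINICAL_SUMMARY) & (meta["scale_id"] == SEVERITY_SCALE_ID)]
        if len(ids) == 0:
            raise ValueError("cohort has no severity-scale total feature")
        return ids[0]

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.values.equals(other.values)
            and self.subjects.equals(other.subjects)
            and self.features.equals(other.features)
        )


def _apportion(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n units to blocks."""
    raw = np.asarray(proportions) * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    return list(sizes)


def _subtype_sizes(n_cases: int, proportions: tuple[float, ...]) -> list[int]:
    sizes = _apportion(n_cases, proportions)
    if n_cases > 0 and any(s == 0 for s in sizes):
        raise ValueError(
            "subtype_proportions incompatible with case count: a planted subtype would be empty"
        )
    return sizes


def _equicorrelated(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m unit-variance Gaussian block with pairwise correlation rho."""
    shared = rng.normal(size=(n, 1))
    eps = rng.normal(size=(n, m))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps


@dataclass
class _Instrument:
    """Frozen per-config item parameters (drawn once from the config seed)."""

    loadings: list[np.ndarray]          # per scale, per item
    difficulties: list[np.ndarray]      # per scale, per item
    item_max: list[int]                 # per scale
    marker_direction: dict              # feature_id -> 'up'/'down'/''
    aux_informative: dict               # class -> boolean mask


def _build_instrument(config: CohortConfig, rng: np.random.Generator) -> _Instrument:
    lo, hi = config.item_loading_range
    loadings, difficulties, item_max = [], [], []
    for s, n_items in enumerate(config.items_per_scale):
        mx = 8 if s == 0 else 4
        base = mx / 8.0
        n_hard = int(round(config.hard_item_fraction * n_items))
        n_easy = n_items - n_hard
        b = np.concatenate(
            [
                config.item_loading * rng.uniform(lo, hi, size=n_easy),
                config.hard_item_loading * rng.uniform(lo, hi, size=n_hard),
            ]
        )
        # the severity scale's hard items sit in the severe tail (they cap
        # its totals); other scales' hard items sit in the subtype gap
        hard_range = config.tail_difficulty_range if s == 0 else config.gap_difficulty_range
        d = np.concatenate(
            [
                rng.uniform(*config.easy_difficulty_range, size=n_easy),
                rng.uniform(*hard_range, size=n_hard),
            ]
        )
        loadings.append(base * b)
        difficulties.append(d)
        item_max.append(mx)

    # spread informative markers over subclasses proportionally to size
    classes = list(config.n_biomarkers_per_class.items())
    total = sum(m for _, m in classes)
    n_inf = min(config.n_informative_markers, total)
    n_up = max(1, round(config.marker_up_fraction * n_inf)) if n_inf else 0
    per_class = _apportion(n_inf, tuple(m / total for _, m in classes)) if n_inf else [0] * len(classes)
    direction: dict[str, str] = {}
    k = 0
    for (name, m), n_c in zip(classes, per_class):
        for j in range(m):
            fid = f"{name}_{j + 1:03d}"
            if j < n_c:
                # the up-regulated minority is assigned first in the
                # metabolite subclass (lactate-like), then wherever needed
                direction[fid] = "up" if k < n_up and (name == "metabolite" or n_up >= n_inf) else "down"
                if direction[fid] == "up":
                    k += 1
            else:
                direction[fid] = ""
    # guarantee the up quota even if no metabolite subclass exists
    if n_inf and k < n_up:
        for fid, d in direction.items():
            if d == "down" and k < n_up:
                direction[fid] = "up"
                k += 1

    aux_informative = {}
    for name in AUX_CLASSES:
        m = DEFAULT_AUX_SIZES[name]
        mask = np.zeros(m, dtype=bool)
        mask[: max(1, m // 2)] = True
        aux_informative[name] = mask
    return _Instrument(loadings, difficulties, item_max, direction, aux_informative)


def _generate_sample(
    config: CohortConfig,
    inst: _Instrument,
    rng: np.random.Generator,
    n_hc: int,
    n_case: int,
    role: str,
    id_prefix: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sizes = _subtype_sizes(n_case, config.subtype_proportions)
    groups = ["hc"] * n_hc + ["case"] * n_case
    subtypes = [""] * n_hc
    sev_mean = np.full(n_hc, config.severity_means[0])
    for s, sz in enumerate(sizes):
        subtypes += [f"S{s + 1}"] * sz
        sev_mean = np.concatenate([sev_mean, np.full(sz, config.severity_means[s + 1])])
    n = n_hc + n_case
    ids = [f"{id_prefix}-{g.upper()}{i + 1:03d}" for i, g in enumerate(groups)]
    z = rng.normal(sev_mean, config.severity_sd)

    cols: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str, str, str]] = []

    # clinical items and per-scale totals
    totals: dict[str, np.ndarray] = {}
    for s in range(config.n_clinical_scales):
        scale_id = SEVERITY_SCALE_ID if s == 0 else f"scale{s + 1:02d}"
        mx = inst.item_max[s]
        tot = np.zeros(n)
        for j, (b, delta) in enumerate(zip(inst.loadings[s], inst.difficulties[s])):
            raw = b * (z - delta) + rng.normal(0.0, config.item_noise_sd, size=n)
            item = np.clip(np.round(raw), 0, mx)
            fid = f"{scale_id}_item{j + 1:02d}"
            cols[fid] = item
            meta_rows.append((fid, CLASS_CLINICAL_ITEM, "", scale_id, ""))
            tot += item
        totals[scale_id] = tot
    for scale_id, tot in totals.items():
        fid = f"{scale_id}_total"
        cols[fid] = tot
        meta_rows.append((fid, CLASS_CLINICAL_SUMMARY, "", scale_id, ""))

    # graded group shift weights: HC 0, subtypes up to 1 for the most severe
    w_by_label = {"": 0.0}
    n_sub = config.n_subtypes()
    grades = [1.0] if n_sub == 1 else list(np.linspace(0.5, 1.0, n_sub))
    for s in range(n_sub):
        w_by_label[f"S{s + 1}"] = grades[s]
    w = np.array([w_by_label[t] for t in subtypes])

    # biomarkers: equicorrelated noise per subclass plus planted shifts
    for name, m in config.n_biomarkers_per_class.items():
        block = _equicorrelated(rng, n, m, config.block_correlation)
        for j in range(m):
            fid = f"{name}_{j + 1:03d}"
            d = inst.marker_direction[fid]
            vals = block[:, j]
            if d == "down":
                vals = vals - config.marker_effect_size * w
            elif d == "up":
                vals = vals + config.marker_effect_size * w
            cols[fid] = vals
            meta_rows.append((fid, CLASS_BIOMARKER, name, "", d))

    # auxiliary classes, analogous but with class-specific effect sizes
    for name in AUX_CLASSES:
        m = DEFAULT_AUX_SIZES[name]
        effect = config.aux_class_effect_sizes.get(name, 0.0)
        block = _equicorrelated(rng, n, m, config.block_correlation)
        informative = inst.aux_informative[name]
        sign = -1.0 if name in AUX_DOWN else 1.0
        for j in range(m):
            fid = f"{name}_{j + 1:02d}"
            vals = block[:, j]
            d = ""
            if informative[j] and effect > 0:
                vals = vals + sign * effect * w
                d = "down" if sign < 0 else "up"
            cols[fid] = vals
            meta_rows.append((fid, name, "", "", d))

    values = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))
    subjects = pd.DataFrame(
        {"group": groups, "role": role, "true_subtype": subtypes},
        index=pd.Index(ids, name="subject_id"),
    )
    features = pd.DataFrame(
        meta_rows, columns=["feature_id", "class", "subclass", "scale_id", "expected_direction"]
    ).set_index("feature_id")
    return values, subjects, features


def generate_cohort(config: CohortConfig | None = None) -> CohortTable:
    """Generate discovery + validation cohorts; bit-identical per seed."""
    config = config or CohortConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_inst, s_disc, s_val = ss.spawn(3)
    inst = _build_instrument(config, np.random.default_rng(s_inst))
    v1, s1, f1 = _generate_sample(
        config, inst, np.random.default_rng(s_disc),
        config.n_hc_discovery, config.n_case_discovery, "discovery", "D",
    )
    v2, s2, _ = _generate_sample(
        config, inst, np.random.default_rng(s_val),
        config.n_hc_validation, config.n_case_validation, "validation", "V",
    )
    table = CohortTable(pd.concat([v1, v2]), pd.concat([s1, s2]), f1)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# on-disk format: <prefix>_matrix.csv, <prefix>_subjects.csv, <prefix>_features.tsv


def write_cohort(table: CohortTable, prefix: str) -> list[str]:
    table.validate()
    paths = [f"{prefix}_matrix.csv", f"{prefix}_subjects.csv", f"{prefix}_features.tsv"]
    table.values.to_csv(paths[0])
    table.subjects.to_csv(paths[1])
    table.features.to_csv(paths[2], sep="\t")
    return paths


def read_cohort(prefix: str) -> CohortTable:
    values = pd.read_csv(f"{prefix}_matrix.csv", index_col="subject_id")
    subjects = pd.read_csv(f"{prefix}_subjects.csv", index_col="subject_id", keep_default_na=False)
    features = pd.read_csv(
        f"{prefix}_features.tsv", sep="\t", index_col="feature_id", keep_default_na=False
    )
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values.index[pd.to_numeric(values[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric value in column {col!r}, row {bad!r}")
    if len(values) != len(subjects):
        raise ValueError("matrix and subject table have different subject counts")
    missing = set(features.index) - set(values.columns)
    if missing:
        raise ValueError(f"features absent from matrix: {sorted(missing)[:5]}")
    table = CohortTable(values, subjects, features.loc[list(values.columns)])
    table.validate()
    return table


def config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain dict (e.g. parsed YAML)."""
    kwargs = {}
    for f in dataclasses.fields(CohortConfig):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return CohortConfig(**kwargs)
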