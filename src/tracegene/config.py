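"""Run configuration: every tunable of the pipeline with its default.

The defaults are the framework's canonical constants (7-cpm expressed call,
preferential-expression threshold 2, 40% paralog identity, GO term sizes
3-100, 20% tissue-specific interaction bound, 64/20/10 embedding geometry,
10x100 imputation, 10 folds, >60 positives per modeled tissue, 0-10 score
range). A flat YAML file with any subset of these keys configures a run;
the resolved configuration is echoed into every stage manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortConfig, EffectSizes


@dataclass
class RunConfig:
    # expression processing
    expressed_cpm: float = 7.0
    low_count_max: int = 10
    pref_threshold: float = 2.0
    # feature construction
    paralog_min_identity: float = 40.0
    go_term_size_range: tuple[int, int] = (3, 100)
    tissue_specific_fraction: float = 0.20
    embedding_dims: int = 64
    embedding_walks: int = 20
    embedding_walk_length: int = 10
    # preprocessing
    impute_iterations: int = 10
    impute_neighbors: int = 100
    # learning
    folds: int = 10
    min_positives: int = 60
    class_weight_pos_neg: float = 0.01
    selection_c_predict: float = 0.1
    selection_c_interpret: float = 2.0
    selection_cap_interpret: int = 50
    score_range: tuple[float, float] = (0.0, 10.0)
    # execution
    seed: int = 0
    threads: int = 1
    # synthetic cohort
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a flat YAML config; unknown keys raise, absent keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = raw.pop("cohort", {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    if "go_term_size_range" in raw:
        raw["go_term_size_range"] = tuple(raw["go_term_size_range"])
    if "score_range" in raw:
        raw["score_range"] = tuple(raw["score_range"])
    cohort_known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(cohort_raw) - cohort_known
    if unknown:
        raise ValueError(f"unknown cohort configuration key(s): {sorted(unknown)}")
    if "effect_sizes" in cohort_raw:
        cohort_raw["effect_sizes"] = EffectSizes(**cohort_raw["effect_sizes"])
    if "tissues" in cohort_raw:
        cohort_raw["tissues"] = tuple(cohort_raw["tissues"])
    if "go_term_size_range" in cohort_raw:
        cohort_raw["go_term_size_range"] = tuple(cohort_raw["go_term_size_range"])
    cfg = RunConfig(**raw, cohort=CohortConfig(**cohort_raw))
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
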