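"""Synthetic multi-omics cohort with planted tissue-selectivity signal.

Generates every input the pipeline consumes — raw counts with a sample ->
tissue map, a developmental organ x timepoint panel, a PPI edge list, GO
annotations, paralog pairs, eQTL q-values, disease-gene associations and
brain-region labels, plus a ``truth`` record of the planted positives and
their mechanisms — so the whole framework can be exercised and benchmarked
without external data.

The planted mechanisms per tissue ``t``:

* expression: positives' expected cpm in ``t`` is shifted by
  ``pref_expr_shift`` log2 units (draws centred on the stated shift);
* process: each positive joins a planted GO term whose co-member genes are
  shifted in ``t`` by ``process_shift`` log2 units, so the term's
  differential activity — and the positive's process features — rise without
  touching the positive's own expression beyond the expression mechanism;
* interactome: positives gain extra PPI edges to genes expressed in ``t``
  (expected degree inflated by ``ppi_density_boost``);
* eQTL: positives' q-values in ``t`` are drawn low (Beta), scaled by
  ``eqtl_shift``; all other cells are uniform on [0, 1].

Setting every effect size to zero yields a full null cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import CountMatrix

DEFAULT_TISSUES = (
    "blood",
    "brain",
    "heart",
    "liver",
    "muscle",
    "nerve",
    "skin",
    "testis",
)
DEFAULT_DEV_ORGANS = (
    "cerebrum",
    "cerebellum",
    "dev_heart",
    "kidney",
    "dev_liver",
    "ovary",
    "dev_testis",
)
BRAIN_REGIONS = ("cortex", "cerebellum_region", "basal_ganglia")


@dataclass
class EffectSizes:
    pref_expr_shift: float = 1.0  # log2 units
    process_shift: float = 1.0  # log2 units
    ppi_density_boost: float = 0.5  # fraction of the mean degree
    eqtl_shift: float = 1.0  # strength of the low-q signal

    def all_zero(self) -> bool:
        return (
            self.pref_expr_shift == 0
            and self.process_shift == 0
            and self.ppi_density_boost == 0
            and self.eqtl_shift == 0
        )


@dataclass
class CohortConfig:
    n_genes: int = 6000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    samples_per_tissue: int = 30
    n_dev_organs: int = 7
    n_dev_timepoints: int = 5
    dev_replicates: int = 3
    frac_disease_genes: float = 0.15
    positives_per_tissue: int = 70
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    ppi_mean_degree: int = 6
    n_go_terms: int = 250
    go_term_size_range: tuple[int, int] = (3, 100)
    paralog_frac: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_disease_genes", "paralog_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"configuration error: {name}={v} not in [0, 1]")
        if self.positives_per_tissue * len(self.tissues) > self.n_genes * self.frac_disease_genes:
            raise ValueError(
                "configuration error: positives_per_tissue x |tissues| exceeds "
                "n_genes x frac_disease_genes"
            )
        lo, hi = self.go_term_size_range
        if not (3 <= lo <= hi <= 100):
            raise ValueError(
                f"configuration error: go_term_size_range={self.go_term_size_range} "
                "must lie within [3, 100]"
            )
        if self.samples_per_tissue < 2:
            raise ValueError("configuration error: samples_per_tissue must be >= 2")
        if self.n_dev_organs > len(DEFAULT_DEV_ORGANS):
            raise ValueError(
                f"configuration error: n_dev_organs at most {len(DEFAULT_DEV_ORGANS)}"
            )


@dataclass
class CohortTruth:
    """Planted ground truth: positives per tissue and their mechanisms."""

    positives: dict[str, list[str]]
    planted_terms: dict[str, list[str]]
    mechanisms: dict[str, list[str]]  # active mechanism names per tissue
    disease_genes: list[str]


@dataclass
class CohortBundle:
    counts: CountMatrix
    dev_expression: pd.DataFrame  # genes x (organ, timepoint, sample)
    ppi_edges: pd.DataFrame  # columns gene_a, gene_b
    go_annotations: pd.DataFrame  # columns term, gene
    paralogs: pd.DataFrame  # columns gene_a, gene_b, identity
    eqtl_q: pd.DataFrame  # genes x tissues, NaN = missing
    associations: pd.DataFrame  # columns disease_id, gene, tissue
    brain_associations: pd.DataFrame  # columns disease_id, gene, region, confidence
    truth: CohortTruth
    config: CohortConfig


def _power_law_weights(n: int, rng: np.random.Generator, alpha: float = 2.5) -> np.ndarray:
    u = rng.random(n)
    w = (1 - u) ** (-1.0 / (alpha - 1.0))  # Pareto, minimum 1
    return np.minimum(w, np.sqrt(n))


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a cohort; deterministic for a fixed config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    tissues = list(config.tissues)
    genes = np.array([f"g{i:05d}" for i in range(n)])

    # --- disease genes & planted positives (uniform draw: no expression bias)
    n_disease = int(round(n * config.frac_disease_genes))
    disease_idx = rng.choice(n, size=n_disease, replace=False)
    pos_per_t = config.positives_per_tissue
    positives: dict[str, np.ndarray] = {}
    cursor = 0
    for t in tissues:
        positives[t] = disease_idx[cursor : cursor + pos_per_t]
        cursor += pos_per_t
    other_disease_idx = disease_idx[cursor:]
    pos_any = np.concatenate([positives[t] for t in tissues])

    # --- expression model: log2 baseline + module effects + tissue modulation
    baseline = rng.normal(4.5, 2.5, size=n)
    n_modules = 20
    module_of = rng.integers(0, n_modules, size=n)
    module_effect = rng.normal(0.0, 0.3, size=(n_modules, len(tissues)))
    modulation = module_effect[module_of] + rng.normal(0.0, 0.3, size=(n, len(tissues)))

    # paralog pairs share dosage: partner baseline tracks its gene
    n_paralog = int(round(n * config.paralog_frac / 2)) * 2
    paralog_idx = rng.choice(n, size=n_paralog, replace=False)
    pa, pb = paralog_idx[: n_paralog // 2], paralog_idx[n_paralog // 2 :]
    baseline[pb] = baseline[pa] + rng.normal(0.0, 0.7, size=pa.size)
    identity = rng.uniform(20.0, 95.0, size=pa.size)
    paralogs = pd.DataFrame(
        {"gene_a": genes[pa], "gene_b": genes[pb], "identity": np.round(identity, 2)}
    )

    # --- planted shifts
    shift = np.zeros((n, len(tissues)))
    es = config.effect_sizes
    planted_terms: dict[str, list[str]] = {t: [] for t in tissues}
    go_rows: list[tuple[str, str]] = []
    term_counter = 0
    for j, t in enumerate(tissues):
        pos = positives[t]
        if es.pref_expr_shift > 0:
            shift[pos, j] += rng.normal(es.pref_expr_shift, 0.2, size=pos.size)
        if es.process_shift <= 0:
            # no planted terms without a process effect: grouping positives
            # into dedicated terms would fingerprint the labels through
            # shared term-activity values even at zero shift
            continue
        # planted GO terms: ~10 positives per term + shifted co-members
        for start in range(0, pos.size, 10):
            group = pos[start : start + 10]
            term = f"GO:P{term_counter:05d}"
            term_counter += 1
            planted_terms[t].append(term)
            n_co = int(rng.integers(8, 15))
            co = rng.choice(np.setdiff1d(np.arange(n), pos_any), size=n_co, replace=False)
            if es.process_shift > 0:
                shift[co, j] += rng.normal(es.process_shift, 0.2, size=co.size)
            for g in np.concatenate([group, co]):
                go_rows.append((term, genes[g]))

    # background GO terms
    lo, hi = config.go_term_size_range
    for k in range(config.n_go_terms):
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))))
        size = min(max(size, lo), hi)
        members = rng.choice(n, size=size, replace=False)
        term = f"GO:B{k:05d}"
        for g in members:
            go_rows.append((term, genes[g]))
    go_annotations = pd.DataFrame(go_rows, columns=["term", "gene"])

    # --- counts (Poisson around expected cpm, per-sample depth + noise)
    log2_cpm = baseline[:, None] + modulation + shift
    expected_cpm = np.power(2.0, log2_cpm)
    sample_ids, sample_tissue, count_cols = [], [], []
    for j, t in enumerate(tissues):
        lib = rng.uniform(0.8e6, 1.2e6, size=config.samples_per_tissue)
        noise = np.power(2.0, rng.normal(0.0, 0.15, size=(n, config.samples_per_tissue)))
        lam = expected_cpm[:, j : j + 1] * noise * (lib[None, :] / 1e6)
        counts_t = rng.poisson(lam)
        count_cols.append(counts_t)
        for s in range(config.samples_per_tissue):
            sample_ids.append(f"{t}_s{s:02d}")
            sample_tissue.append(t)
    counts = pd.DataFrame(
        np.concatenate(count_cols, axis=1), index=genes, columns=sample_ids
    )
    tissue_of = pd.Series(sample_tissue, index=sample_ids, name="tissue")

    # --- developmental panel (normalized counts; no planted signal)
    organs = list(DEFAULT_DEV_ORGANS[: config.n_dev_organs])
    dev_cols = []
    dev_data = []
    dev_base = baseline * 0.8
    for organ in organs:
        organ_eff = rng.normal(0.0, 0.5, size=n)
        for tp in range(config.n_dev_timepoints):
            tp_eff = rng.normal(0.0, 0.4, size=n)
            for r in range(config.dev_replicates):
                noise = rng.normal(0.0, 0.2, size=n)
                dev_data.append(np.power(2.0, dev_base + organ_eff + tp_eff + noise))
                dev_cols.append((organ, f"tp{tp}", f"r{r}"))
    dev_expression = pd.DataFrame(
        np.stack(dev_data, axis=1),
        index=genes,
        columns=pd.MultiIndex.from_tuples(dev_cols, names=["organ", "timepoint", "sample"]),
    )

    # --- PPI graph: Chung-Lu with power-law weights, intra-module edge boost,
    # then planted extra edges for positives toward tissue-expressed genes
    w = _power_law_weights(n, rng) * (config.ppi_mean_degree / 2.0)
    s = w.sum()
    m_target = int(config.ppi_mean_degree * n / 2)
    src = rng.choice(n, size=m_target * 2, p=w / s)
    dst = rng.choice(n, size=m_target * 2, p=w / s)
    same_module = module_of[src] == module_of[dst]
    keep = rng.random(src.size) < np.where(same_module, 1.0, 0.45)
    edges = np.stack([src[keep], dst[keep]], axis=1)
    edges = edges[edges[:, 0] != edges[:, 1]]
    edges = np.unique(np.sort(edges, axis=1), axis=0)

    extra_edges = []
    if es.ppi_density_boost > 0:
        # proxy for "expressed in t": expected cpm above the expressed threshold
        for j, t in enumerate(tissues):
            expressed_proxy = np.where(expected_cpm[:, j] >= 7.0)[0]
            n_extra = max(1, int(round(es.ppi_density_boost * config.ppi_mean_degree)))
            for g in positives[t]:
                targets = rng.choice(expressed_proxy, size=n_extra, replace=False)
                for tgt in targets:
                    if tgt != g:
                        extra_edges.append((min(g, tgt), max(g, tgt)))
    if extra_edges:
        edges = np.unique(np.concatenate([edges, np.array(extra_edges)]), axis=0)
    ppi_edges = pd.DataFrame(
        {"gene_a": genes[edges[:, 0]], "gene_b": genes[edges[:, 1]]}
    )

    # --- eQTL q-values
    eqtl = rng.random((n, len(tissues)))
    if es.eqtl_shift > 0:
        for j, t in enumerate(tissues):
            pos = positives[t]
            eqtl[pos, j] = rng.beta(1.0, 1.0 + 9.0 * es.eqtl_shift, size=pos.size)
    miss = rng.random((n, len(tissues))) < 0.2
    eqtl[miss] = np.nan
    eqtl_q = pd.DataFrame(eqtl, index=genes, columns=tissues)

    # --- labels
    assoc_rows = []
    for t in tissues:
        for k, g in enumerate(positives[t]):
            assoc_rows.append((f"D_{t}_{k:03d}", genes[g], t))
    for k, g in enumerate(other_disease_idx):
        assoc_rows.append((f"D_other_{k:03d}", genes[g], "other_tissue"))
    associations = pd.DataFrame(assoc_rows, columns=["disease_id", "gene", "tissue"])

    brain_rows = []
    if "brain" in tissues:
        for k, g in enumerate(positives["brain"]):
            region = BRAIN_REGIONS[int(rng.integers(0, len(BRAIN_REGIONS)))]
            conf = int(rng.integers(1, 4))
            brain_rows.append((f"D_brain_{k:03d}", genes[g], region, conf))
    brain_associations = pd.DataFrame(
        brain_rows, columns=["disease_id", "gene", "region", "confidence"]
    )

    mechanisms = {
        t: [
            name
            for name, active in [
                ("expression", es.pref_expr_shift > 0),
                ("process", es.process_shift > 0),
                ("ppi", es.ppi_density_boost > 0),
                ("eqtl", es.eqtl_shift > 0),
            ]
            if active
        ]
        for t in tissues
    }
    truth = CohortTruth(
        positives={t: [str(g) for g in genes[positives[t]]] for t in tissues},
        planted_terms=planted_terms,
        mechanisms=mechanisms,
        disease_genes=[str(g) for g in genes[disease_idx]],
    )
    return CohortBundle(
        counts=CountMatrix(values=counts, tissue_of=tissue_of),
        dev_expression=dev_expression,
        ppi_edges=ppi_edges,
        go_annotations=go_annotations,
        paralogs=paralogs,
        eqtl_q=eqtl_q,
        associations=associations,
        brain_associations=brain_associations,
        truth=truth,
        config=config,
    )


@dataclass
class PatientCase:
    patient_id: str
    affected_tissues: list[str]
    candidates: list[str]
    verified_gene: str | None = None

    def __post_init__(self) -> None:
        if self.verified_gene is not None and self.verified_gene not in self.candidates:
            raise ValueError(
                f"verified gene {self.verified_gene} missing from candidate list"
            )


def generate_patient_cases(
    bundle: CohortBundle,
    n_patients: int,
    candidates_per_patient: int,
    seed: int,
    universe: pd.Index | None = None,
) -> list[PatientCase]:
    """Benchmark patients: one affected tissue, one verified gene drawn from
    that tissue's planted positives, and decoys drawn from non-positive genes.

    ``universe`` restricts candidates to genes that survive the expression
    filters (pass the feature-table gene index); by default genes whose raw
    count never exceeds the low-count threshold are excluded.
    """
    if candidates_per_patient < 2:
        raise ValueError("candidates_per_patient must be >= 2 (no decoys possible)")
    if not any(bundle.truth.positives.values()):
        raise ValueError("cohort truth has no planted positives")
    rng = np.random.default_rng(seed)
    tissues = [t for t, p in bundle.truth.positives.items() if p]
    if universe is None:
        retained = bundle.counts.values.max(axis=1) > 10
        universe = bundle.counts.values.index[retained]
    pos_any = set().union(*(set(p) for p in bundle.truth.positives.values()))
    decoy_pool = np.array([g for g in universe if g not in pos_any])
    cases = []
    for i in range(n_patients):
        t = tissues[i % len(tissues)]
        tissue_pos = [g for g in bundle.truth.positives[t] if g in set(universe)]
        if not tissue_pos:
            raise ValueError(f"tissue {t!r} has no planted positives in the universe")
        verified = str(rng.choice(tissue_pos))
        decoys = rng.choice(decoy_pool, size=candidates_per_patient - 1, replace=False)
        candidates = [verified] + [str(g) for g in decoys]
        order = rng.permutation(len(candidates))
        candidates = [candidates[k] for k in order]
        cases.append(
            PatientCase(
                patient_id=f"patient_{i:03d}",
                affected_tissues=[t],
                candidates=candidates,
                verified_gene=verified,
            )
        )
    return cases
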