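"""End-to-end orchestration and cohort descriptive statistics.

:func:`run_pipeline` sequences the full analysis — synthetic-cohort
generation (or TSV input), preprocessing, Table-1-style descriptives,
per-ASV univariate screening, stage-1 clique discovery per modifier
stratum, and stage-2 inference with cross-stratum validation, an
interaction test and balance diagnostics — writing every report as TSV
plus a JSON manifest, fully reproducible from config + master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .containers import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    MODIFIER,
    OUTCOME,
    OUTCOME_RAW,
    STRATUM_INSECURE,
    STRATUM_SECURE,
    AbundanceTable,
    CohortTable,
    ConfigError,
    MicaError,
)
from . import discovery, inference, preprocess, synthio, univariate


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    sim: synthio.SimConfig | None = None
    abundance_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    prevalence_threshold: float = 0.05
    rh_sirf: discovery.RhSirfConfig = field(
        default_factory=lambda: discovery.RhSirfConfig(n_repeats=100, n_bootstraps=25)
    )
    n_permutations: int = 10_000
    n_subclasses: int = 5
    pmm_donors: int = 5
    min_stratum_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and (self.abundance_path is None or self.metadata_path is None):
            raise ConfigError("provide either a SimConfig or abundance+metadata paths")

    def config_hash(self) -> str:
        payload = {
            "sim": asdict(self.sim) if self.sim else None,
            "paths": [self.abundance_path, self.metadata_path, self.taxonomy_path],
            "prevalence_threshold": self.prevalence_threshold,
            "rh_sirf": asdict(self.rh_sirf),
            "n_permutations": self.n_permutations,
            "n_subclasses": self.n_subclasses,
            "pmm_donors": self.pmm_donors,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=_jsonable)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def cohort_descriptives(cohort: CohortTable, table: AbundanceTable | None = None) -> pd.DataFrame:
    """Table-1-style per-stratum summary.

    Continuous variables: mean (SD) per stratum with a Wilcoxon rank-sum
    (Mann–Whitney) p-value. Categorical variables: n (%) with Fisher's
    exact p for 2×2, chi-square for more levels. Includes Shannon
    diversity (if an abundance table is given) and the cognitive score.
    """
    data = cohort.data
    secure = data[data[MODIFIER] == 0]
    insecure = data[data[MODIFIER] == 1]
    rows = []

    continuous = list(CONTINUOUS_COVARIATES) + [OUTCOME_RAW]
    shannon = None
    if table is not None:
        shannon = pd.Series(
            [preprocess.shannon_diversity(row) for row in table.data.to_numpy()],
            index=table.sample_ids, name="shannon",
        )
    for var in continuous + (["shannon"] if shannon is not None else []):
        a = shannon.loc[secure.index] if var == "shannon" else secure[var]
        b = shannon.loc[insecure.index] if var == "shannon" else insecure[var]
        a, b = a.dropna(), b.dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "variable": var, "type": "continuous",
            "secure": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
            "insecure": f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
            "p_value": p, "test": "wilcoxon-rank-sum",
        })
    for var in BINARY_COVARIATES:
        tab = pd.crosstab(data[var], data[MODIFIER]).reindex(
            index=[0, 1], columns=[0, 1], fill_value=0)
        p = float(stats.fisher_exact(tab.to_numpy())[1])
        n_sec, n_ins = len(secure), len(insecure)
        rows.append({
            "variable": var, "type": "binary",
            "secure": f"{tab.loc[1, 0]} ({100 * tab.loc[1, 0] / max(n_sec, 1):.1f}%)",
            "insecure": f"{tab.loc[1, 1]} ({100 * tab.loc[1, 1] / max(n_ins, 1):.1f}%)",
            "p_value": p, "test": "fisher-exact",
        })
    return pd.DataFrame(rows)


def _load_inputs(cfg: PipelineConfig) -> tuple[AbundanceTable, CohortTable]:
    if cfg.sim is not None:
        sim = cfg.sim
        return synthio.simulate_cohort(sim)
    taxonomy = {}
    if cfg.taxonomy_path:
        tx = pd.read_csv(cfg.taxonomy_path, sep="\t", index_col=0)
        taxonomy = tx.iloc[:, 0].to_dict()
    table = AbundanceTable.from_tsv(cfg.abundance_path, taxonomy=taxonomy)
    cohort = CohortTable.from_tsv(cfg.metadata_path)
    return table, cohort


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write reports under ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``):
    config hash, seed, package/library versions, and row/taxon counts at
    each filtering step (non-increasing by construction).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    table, cohort = _load_inputs(cfg)
    counts["samples_input"] = table.n_samples
    counts["taxa_input"] = table.n_taxa

    # analytical sample: complete modifier and outcome
    complete = cohort.data[MODIFIER].notna() & cohort.data[OUTCOME_RAW].notna()
    cohort = CohortTable(cohort.data.loc[complete])
    table = AbundanceTable(table.data.loc[cohort.sample_ids], table.taxonomy, table.is_relative)
    counts["samples_analytical"] = table.n_samples

    if not table.is_relative:
        table = preprocess.to_relative_abundance(table)
    filtered = preprocess.prevalence_filter(table, cfg.prevalence_threshold)
    counts["taxa_retained"] = filtered.n_taxa

    cohort = preprocess.pmm_impute(cohort, donors=cfg.pmm_donors, seed=cfg.seed + 11)
    cohort = preprocess.add_transformed_outcome(cohort)

    descriptives = cohort_descriptives(cohort, table)
    descriptives.to_csv(out / "descriptives.tsv", sep="\t", index=False,
                        float_format="%.6g")

    # univariate screening per stratum + volcano tables
    screen_frames = []
    volcano_frames = []
    for stratum in (STRATUM_SECURE, STRATUM_INSECURE):
        results = univariate.asv_screen(filtered, cohort, stratum, min_n=cfg.min_stratum_n)
        screen_frames.append(univariate.results_frame(results))
        volcano_frames.append(univariate.volcano_table(results, filtered.taxonomy))
    pd.concat(screen_frames).to_csv(out / "asv_screen.tsv", sep="\t", index=False,
                                    float_format="%.6g")
    pd.concat(volcano_frames).to_csv(out / "volcano.tsv", sep="\t", index=False,
                                     float_format="%.6g")

    # stage 1 per stratum
    stage1_rows = []
    cliques_by_stratum: dict[str, list[discovery.CliqueDefinition]] = {}
    for k, stratum in enumerate((STRATUM_SECURE, STRATUM_INSECURE)):
        mask = cohort.stratum_mask(stratum).to_numpy()
        X = filtered.data.to_numpy()[mask]
        y = cohort.data.loc[mask, OUTCOME].to_numpy()
        rcfg = discovery.RhSirfConfig(**{**asdict(cfg.rh_sirf),
                                         "seed": cfg.seed + 101 * (k + 1)})
        report = discovery.stability_analysis(X, y, rcfg)
        cliques = discovery.select_cliques_closed_loop(
            report.taxon_sets, stability_threshold=rcfg.stability_threshold)
        cliques_by_stratum[stratum] = cliques
        selected_taxa = {j for c in cliques for j in c.members}
        for s in report.itemsets:
            if len(s) < 2:
                continue
            stage1_rows.append({
                "stratum": stratum,
                "itemset": ";".join(f"{filtered.taxon_ids[j]}:{sign}"
                                    for j, sign in sorted(s.features)),
                "frequency": s.frequency,
                "stability": s.stability,
                "selected": s.taxa <= selected_taxa and len(s.taxa) >= 2,
            })
    pd.DataFrame(stage1_rows, columns=["stratum", "itemset", "frequency",
                                       "stability", "selected"]) \
        .to_csv(out / "stage1_itemsets.tsv", sep="\t", index=False, float_format="%.6g")

    edge_rows = [
        {"stratum": stratum,
         "clique": c.name,
         "source": filtered.taxon_ids[a], "target": filtered.taxon_ids[b]}
        for stratum, cliques in cliques_by_stratum.items()
        for c in cliques
        for a, b in zip(c.members, c.members[1:] + c.members[:1])
    ]
    pd.DataFrame(edge_rows, columns=["stratum", "clique", "source", "target"]) \
        .to_csv(out / "clique_network_edges.tsv", sep="\t", index=False)

    # stage 2
    stage2 = []
    balance_frames = []
    for stratum, cliques in cliques_by_stratum.items():
        for c in cliques:
            members = [filtered.taxon_ids[j] for j in c.members]
            ind = inference.clique_indicator(filtered, members, c.name)
            assoc = inference.clique_association(
                cohort, ind, stratum, n_permutations=cfg.n_permutations,
                seed=cfg.seed + 7)
            stage2.append({**assoc.to_dict(), "role": "discovery", "clique": c.name,
                           "members": "+".join(members)})
            val = inference.cross_stratum_validate(
                cohort, ind, stratum, n_permutations=cfg.n_permutations,
                seed=cfg.seed + 8)
            if val is not None:
                stage2.append({**val.to_dict(), "role": "validation", "clique": c.name,
                               "members": "+".join(members)})
            inter = inference.interaction_test(
                cohort, ind, n_permutations=cfg.n_permutations, seed=cfg.seed + 9)
            stage2.append({**inter.to_dict(), "role": "interaction", "clique": c.name,
                           "members": "+".join(members)})
            bal = inference.balance_diagnostics(cohort, ind, cfg.n_subclasses)
            bal.insert(0, "clique", c.name)
            bal.insert(1, "stratum", stratum)
            balance_frames.append(bal)
    stage2_cols = ["clique", "members", "role", "stratum", "term", "beta", "se",
                   "ci_low", "ci_high", "p_raw", "q_fdr", "p_perm", "n_perm", "n"]
    pd.DataFrame(stage2, columns=stage2_cols).to_csv(
        out / "stage2_associations.tsv", sep="\t", index=False, float_format="%.6g")
    if balance_frames:
        pd.concat(balance_frames).to_csv(out / "balance.tsv", sep="\t", index=False,
                                         float_format="%.6g")
    else:
        pd.DataFrame(columns=["clique", "stratum", "covariate",
                              "smd_before", "smd_after"]).to_csv(
            out / "balance.tsv", sep="\t", index=False)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"mica": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "counts": counts,
        "cliques": {stratum: [list(c.members) for c in cliques]
                    for stratum, cliques in cliques_by_stratum.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
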