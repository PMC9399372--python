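"""End-to-end orchestration of the radiosensitivity signature screen.

Funnel: ANOVA time-response filter -> model-profile clustering with
permutation significance -> cluster-eigengene vs SF2 screen -> single-gene
forest / SGLQ fail-both exclusion -> multi-omics union network and
median-centrality hub call.  Final candidates are the retained genes that are
also network hubs; hypergeometric over-representation annotates the result.

Every stage logs its parameters, seed and counts, and the whole run is
deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as rio
from . import omicsnet, radioscreen, singlegene, timecourse
from .exceptions import StageError

log = logging.getLogger("radiosig")

__all__ = [
    "PipelineConfig",
    "CandidateReport",
    "run_pipeline",
    "funnel_summary",
    "stage_percentages",
    "ora_enrichment",
    "evaluate_against_truth",
]


@dataclass
class StemConfig:
    c: int = 2
    m: int = 50
    n_perm: int = 1000
    q_threshold: float = 0.01
    method: str = "binomial"


@dataclass
class ScreenConfig:
    threshold: float = 0.1
    signed: bool = False


@dataclass
class SingleGeneConfig:
    sglq_p_threshold: float = 0.05
    rf_trees: int = 500
    rf_max_features: float = 1.0 / 3.0


@dataclass
class NetworkConfig:
    restart_beta: float = 0.4
    delta: float | None = None
    delta_quantile: float = 0.999
    k_min: int = 3
    protein_min_weight: float = 0.7
    coexpr_power: float = 6.0
    coexpr_min_module_size: int = 30
    coexpr_cut_height: float = 0.99
    coexpr_merge_corr: float = 0.75
    coexpr_edge_quantile: float = 0.9
    hub_scope: str = "full"  # 'full' or 'candidates'
    closeness: str = "harmonic"  # 'harmonic' or 'classic'


@dataclass
class PipelineConfig:
    """All stage parameters; serializable to/from YAML with round-trip equality."""

    anova_alpha: float = 0.05
    stem: StemConfig = field(default_factory=StemConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    singlegene: SingleGeneConfig = field(default_factory=SingleGeneConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    ora_q_threshold: float = 0.05
    seed: int = 20220810

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("stem", StemConfig),
            ("screen", ScreenConfig),
            ("singlegene", SingleGeneConfig),
            ("network", NetworkConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class FunnelStage:
    stage: str
    n_in: int
    n_out: int

    @property
    def pct_retained(self) -> float:
        return stage_percentages(self.n_in - self.n_out, self.n_in)[1]

    @property
    def pct_excluded(self) -> float:
        return stage_percentages(self.n_in - self.n_out, self.n_in)[0]


def stage_percentages(n_excluded: int, n_total: int) -> tuple[float, float]:
    """(excluded %, retained %) of a funnel stage, one-decimal rounding."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    pct_exc = round(100.0 * n_excluded / n_total, 1)
    pct_ret = round(100.0 * (n_total - n_excluded) / n_total, 1)
    return pct_exc, pct_ret


@dataclass
class CandidateReport:
    """Ranked candidates plus per-stage evidence and the stage funnel."""

    candidates: list
    evidence: pd.DataFrame
    funnel: list  # of FunnelStage
    cluster_screen: pd.DataFrame | None = None
    exclusion: singlegene.ExclusionReport | None = None
    hub_report: omicsnet.HubReport | None = None
    enrichment: pd.DataFrame | None = None
    truth_metrics: dict | None = None
    note: str | None = None

    def to_json(self) -> str:
        payload = {
            "candidates": list(self.candidates),
            "funnel": [dataclasses.asdict(s) for s in self.funnel],
            "note": self.note,
            "truth_metrics": self.truth_metrics,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.evidence.to_csv(d / "candidates.tsv", sep="\t")
        funnel = [
            dict(
                stage=s.stage,
                n_in=s.n_in,
                n_out=s.n_out,
                pct_retained=s.pct_retained,
                pct_excluded=s.pct_excluded,
            )
            for s in self.funnel
        ]
        (d / "funnel.json").write_text(json.dumps(funnel, indent=1))
        if self.enrichment is not None:
            self.enrichment.to_csv(d / "enrichment.tsv", sep="\t", index=False)
        (d / "report.json").write_text(self.to_json())


def _empty_report(funnel, note) -> CandidateReport:
    log.info("pipeline stopped early: %s", note)
    return CandidateReport(
        candidates=[],
        evidence=pd.DataFrame(),
        funnel=funnel,
        note=note,
    )


def run_pipeline(
    bundle: rio.Bundle | str | Path, config: PipelineConfig | None = None
) -> CandidateReport:
    """Execute the full discovery funnel on a bundle (object or directory).

    A run with no significant time-course clusters returns an empty report
    with an explanatory note (the expected outcome on null data); any later
    stage emptying out raises :class:`StageError` naming the stage.
    """
    if not isinstance(bundle, rio.Bundle):
        bundle = rio.read_bundle(bundle)
    cfg = config or PipelineConfig()
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    expr = bundle.expression
    sf2 = bundle.sf2
    funnel: list[FunnelStage] = []
    n_genes = len(expr.genes)

    # 1. time-response filter
    anova_p = timecourse.anova_filter(expr, alpha=cfg.anova_alpha)
    funnel.append(FunnelStage("anova", n_genes, len(anova_p)))
    log.info("anova: %d/%d genes at p<%g", len(anova_p), n_genes, cfg.anova_alpha)
    if len(anova_p) == 0:
        raise StageError("anova", "no time-responsive genes")

    # 2. profile clustering + permutation significance
    series = expr.mean_series().loc[anova_p.index]
    lib = timecourse.build_profile_library(
        series.shape[1], c=cfg.stem.c, m=cfg.stem.m
    )
    assignment = timecourse.assign_genes(series, lib)
    assignment = timecourse.profile_significance(
        assignment,
        n_perm=cfg.stem.n_perm,
        q_threshold=cfg.stem.q_threshold,
        method=cfg.stem.method,
        seed=seeds[0],
    )
    sig_profiles = assignment.significant_profiles()
    members = {int(p): list(assignment.members(p)) for p in sig_profiles}
    clustered = sorted(set().union(*members.values())) if members else []
    funnel.append(FunnelStage("profile_clusters", len(anova_p), len(clustered)))
    log.info(
        "profiles: %d significant clusters (q<%g), %d genes",
        len(sig_profiles),
        cfg.stem.q_threshold,
        len(clustered),
    )
    if not members:
        return _empty_report(
            funnel, f"no profile cluster significant at q<{cfg.stem.q_threshold}"
        )

    # 3. cluster eigengene vs SF2 screen (untreated = earliest timepoint)
    baseline = expr.baseline()
    eigs = [
        radioscreen.cluster_eigenvalue(baseline, genes, cluster_id=pid)
        for pid, genes in sorted(members.items())
    ]
    screen = radioscreen.screen_clusters(
        eigs, sf2, threshold=cfg.screen.threshold, signed=cfg.screen.signed
    )
    passing = screen.loc[screen["selected"], "cluster_id"].tolist()
    candidates = sorted(set().union(*(members[p] for p in passing))) if passing else []
    funnel.append(FunnelStage("sf2_cluster_screen", len(clustered), len(candidates)))
    log.info("screen: %d/%d clusters pass, %d genes", len(passing), len(eigs), len(candidates))
    if not candidates:
        raise StageError("sf2_cluster_screen", "no cluster correlates with SF2")

    # 4. single-gene fail-both exclusion
    sglq_fits = {
        g: singlegene.fit_sglq(
            baseline.loc[g], sf2, p_threshold=cfg.singlegene.sglq_p_threshold
        )
        for g in candidates
    }
    rf = singlegene.rf_importance(
        baseline.loc[candidates],
        sf2,
        n_trees=cfg.singlegene.rf_trees,
        max_features=cfg.singlegene.rf_max_features,
        seed=int(seeds[1].generate_state(1)[0] % (2**31 - 1)),
    )
    retained, exclusion = singlegene.fail_both_filter(rf, sglq_fits)
    funnel.append(FunnelStage("fail_both_filter", len(candidates), len(retained)))
    log.info(
        "fail-both: %d excluded (%.1f%%), %d retained (%.1f%%)",
        exclusion.n_excluded,
        exclusion.pct_excluded,
        exclusion.n_retained,
        exclusion.pct_retained,
    )
    if not retained:
        raise StageError("fail_both_filter", "every candidate failed both models")

    # 5. multi-omics network + hub screen
    net = cfg.network
    protein_graph = rio.edges_to_graph(bundle.edges, min_weight=net.protein_min_weight)
    layers = []
    for kind in ("mutation", "cna"):
        layer = omicsnet.NetworkLayer(
            kind=kind, graph=protein_graph, heat=bundle.heats[kind]
        )
        diff = omicsnet.diffuse_heat(
            layer,
            restart_beta=net.restart_beta,
            delta=net.delta,
            delta_quantile=net.delta_quantile,
            k_min=net.k_min,
        )
        log.info("%s diffusion: delta=%.3g, %d hot edges", kind, diff.delta, len(diff.hot_edges))
        layers.append(diff)
    trait = sf2.reindex(expr.values.columns.get_level_values("cell_line"))
    trait.index = expr.values.columns
    _, coexpr = omicsnet.coexpression_layer(
        expr.values,
        trait=trait,
        power=net.coexpr_power,
        min_module_size=net.coexpr_min_module_size,
        cut_height=net.coexpr_cut_height,
        merge_corr=net.coexpr_merge_corr,
        edge_quantile=net.coexpr_edge_quantile,
    )
    layers.extend([coexpr, omicsnet.NetworkLayer(kind="protein", graph=protein_graph)])
    scope_nodes = None if net.hub_scope == "full" else retained
    union = omicsnet.union_graph(layers, candidates=scope_nodes)
    hub_report = omicsnet.hub_screen(union, closeness=net.closeness)
    hubs = set(hub_report.hubs)
    final = [g for g in retained if g in hubs]
    funnel.append(FunnelStage("hub_screen", len(retained), len(final)))
    log.info("hubs: %d of %d nodes; %d final candidates", len(hubs), union.number_of_nodes(), len(final))
    if not final:
        raise StageError("hub_screen", "no retained gene is a network hub")

    # ranked evidence table
    cluster_of = {g: pid for pid, genes in members.items() for g in genes}
    rho_of = dict(zip(screen["cluster_id"], screen["rho"]))
    cent = hub_report.centralities
    rows = []
    for g in final:
        fit = sglq_fits[g]
        rows.append(
            {
                "gene": g,
                "cluster_id": cluster_of[g],
                "cluster_rho": rho_of[cluster_of[g]],
                "rf_importance": float(rf.loc[g, "rf_importance"]),
                "rf_pass": bool(rf.loc[g, "rf_pass"]),
                "sglq_alpha": fit.alpha,
                "sglq_beta": fit.beta,
                "sglq_f_pvalue": fit.f_pvalue,
                "sglq_pass": fit.sglq_pass,
                "degree": float(cent.loc[g, "degree"]) if g in cent.index else 0.0,
                "betweenness": float(cent.loc[g, "betweenness"]) if g in cent.index else 0.0,
                "closeness": float(cent.loc[g, "closeness"]) if g in cent.index else 0.0,
                "is_hub": True,
            }
        )
    evidence = (
        pd.DataFrame(rows)
        .sort_values(["degree", "betweenness", "gene"], ascending=[False, False, True])
        .set_index("gene")
    )
    ordered = list(evidence.index)

    enrichment = None
    if bundle.gene_sets:
        enrichment = ora_enrichment(ordered, list(expr.genes), bundle.gene_sets)

    truth_metrics = None
    if bundle.truth is not None:
        truth_metrics = evaluate_against_truth(ordered, bundle.truth)

    return CandidateReport(
        candidates=ordered,
        evidence=evidence,
        funnel=funnel,
        cluster_screen=screen,
        exclusion=exclusion,
        hub_report=hub_report,
        enrichment=enrichment,
        truth_metrics=truth_metrics,
    )


def funnel_summary(report: CandidateReport) -> pd.DataFrame:
    """Stage-by-stage genes in/out with one-decimal percentages."""
    rows = []
    for s in report.funnel:
        pct_exc, pct_ret = stage_percentages(s.n_in - s.n_out, s.n_in)
        rows.append(
            {
                "stage": s.stage,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "pct_retained": pct_ret,
                "pct_excluded": pct_exc,
            }
        )
    return pd.DataFrame(rows)


def ora_enrichment(hits, universe, gene_sets: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    One-sided upper-tail p per set (sets intersected with the universe),
    BH-adjusted across sets.  ``hits`` must be a subset of ``universe``.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits:
        raise ValueError("empty hit set")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        K = len(members)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"gene_set": name, "set_size": K, "overlap": k, "pvalue": p})
    df = pd.DataFrame(rows)
    df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df.sort_values(["pvalue", "gene_set"]).reset_index(drop=True)


def evaluate_against_truth(candidates, truth) -> dict:
    """Precision/recall of the final candidates against the planted set."""
    planted = set(
        truth["signature_genes"] if isinstance(truth, dict) else truth.signature_genes
    )
    found = set(candidates)
    tp = len(found & planted)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(planted) if planted else 0.0
    return {
        "n_candidates": len(found),
        "n_planted": len(planted),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }
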