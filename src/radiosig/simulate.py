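"""Synthetic data generator with planted radiosensitivity signature genes.

Every input the discovery pipeline consumes can be generated here with the
statistical structure the analysis assumes, together with a ground-truth
record, so each stage is verifiable without external downloads:

* a post-irradiation time-course matrix in which planted "signature" genes
  follow one of a few piecewise-linear temporal archetypes while background
  genes are time-independent noise;
* per-cell-line SF2 values tied to the signature genes' baseline expression
  through the SGLQ law SF = exp(alpha*E - beta*E^2), perturbed on the log
  scale and clipped to (0, 1];
* an interaction network in which signature genes are rewired into a dense
  connected subgraph, with elevated mutation / copy-number "heat";
* background co-expression blocks so module discovery has structure to find.

Expression is emitted already z-scored per gene across samples; cell lines
share a latent radiosensitivity factor that correlates the signature genes'
baselines (and hence SF2) across lines.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as rio
from .exceptions import ConfigurationError, GenerationError
from .timecourse import TimeCourseExperiment, build_profile_library

DEFAULT_SEED = 20220810

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_timecourse",
    "simulate_sf2",
    "simulate_network_layers",
    "write_fixture_bundle",
    "simulate_bundle",
]


@dataclass
class SimulationConfig:
    """Generator settings; the defaults define the reference study conditions.

    Sizes mirror a modest discovery screen: 2,000 genes measured on a panel
    of 16 cell lines at six timepoints after 2 Gy irradiation, with 20
    planted signature genes split over two temporal archetypes.
    """

    n_genes: int = 2000
    n_signature: int = 20
    cell_lines: tuple = tuple(f"CL{i:02d}" for i in range(1, 17))
    timepoints_h: tuple = (0, 2, 4, 8, 12, 24)
    n_profiles: int = 2
    profile_amplitude: float = 1.5  # peak deviation of an archetype, z units
    profile_max_change: int = 2  # |unit change| bound per interval (c)
    noise_sd: float = 0.5  # expression noise, z units
    baseline_latent_corr: float = 0.9  # signature baseline vs line latent
    sglq_alpha: float = 0.3  # per expression unit
    sglq_beta: float = 0.3
    sf2_log_noise_sd: float = 0.05
    heat_scale: float = 0.05  # background mean heat (exponential)
    heat_elevation: float = 5.0  # signature heat mean multiplier
    network_mean_degree: float = 8.0  # ER background graph
    signature_density: float = 0.8  # planted subgraph edge probability
    n_coexpr_blocks: int = 4
    coexpr_block_size: int = 60
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_h, dtype=float)
        if not (np.diff(tp) > 0).all():
            raise ConfigurationError("timepoints must be strictly increasing")
        if not 0 <= self.n_signature < self.n_genes:
            raise ConfigurationError("need 0 <= n_signature < n_genes")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_profiles < 1 or (
            self.n_signature and self.n_profiles > max(self.n_signature, 1)
        ):
            raise ConfigurationError("n_profiles must be in [1, n_signature]")
        if not 0 <= self.signature_density <= 1:
            raise ConfigurationError("signature_density must be in [0, 1]")
        if self.heat_elevation <= 0 or self.heat_scale <= 0:
            raise ConfigurationError("heat parameters must be positive")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ConfigurationError("cell line identifiers must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def signature_genes(self, genes=None) -> list[str]:
        genes = list(genes) if genes is not None else self.gene_ids
        return genes[: self.n_signature]

    def _seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("timecourse", "sf2", "network", "heat"), children))


@dataclass
class GroundTruth:
    """Record of what was planted, for downstream evaluation."""

    signature_genes: list
    alpha: dict  # gene -> planted SGLQ alpha
    beta: dict
    profile: dict  # gene -> planted archetype id
    mutation_heat: dict
    cna_heat: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def planted_archetypes(cfg: SimulationConfig) -> np.ndarray:
    """The planted temporal archetype curves, scaled to peak amplitude.

    Archetypes are maximally separated unit-change profiles (the same family
    the clustering stage searches), normalized so the largest absolute
    deviation equals ``profile_amplitude``.
    """
    lib = build_profile_library(
        len(cfg.timepoints_h), c=cfg.profile_max_change, m=cfg.n_profiles
    )
    series = lib.series
    peak = np.abs(series).max(axis=1, keepdims=True)
    return cfg.profile_amplitude * series / peak


def simulate_timecourse(cfg: SimulationConfig) -> TimeCourseExperiment:
    """Simulate the post-irradiation expression matrix (z-scored per gene).

    Signature genes follow their planted archetype plus Gaussian noise;
    background genes are time-independent noise around a per-line baseline.
    Baselines of signature genes are correlated across lines through a latent
    per-line radiosensitivity factor.
    """
    rng = np.random.default_rng(cfg._seeds()["timecourse"])
    genes = cfg.gene_ids
    lines = list(cfg.cell_lines)
    hours = list(cfg.timepoints_h)
    n_sig = cfg.n_signature
    G, L, T = cfg.n_genes, len(lines), len(hours)

    latent = rng.standard_normal(L)  # per-line radiosensitivity factor
    # background genes are pure time-independent noise (no per-line level),
    # so the timepoint ANOVA is exactly calibrated on them
    baseline = np.zeros((G, L))
    if n_sig:
        rho = cfg.baseline_latent_corr
        baseline[:n_sig] = rho * latent[None, :] + np.sqrt(
            1.0 - rho**2
        ) * rng.standard_normal((n_sig, L))
    # background co-expression blocks (time-independent latent per block)
    start = n_sig
    for _ in range(cfg.n_coexpr_blocks):
        stop = min(start + cfg.coexpr_block_size, G)
        if stop <= start:
            break
        block_latent = rng.standard_normal(L)
        rho_b = 0.9
        baseline[start:stop] = rho_b * block_latent[None, :] + np.sqrt(
            1.0 - rho_b**2
        ) * rng.standard_normal((stop - start, L))
        start = stop

    values = np.repeat(baseline[:, :, None], T, axis=2).astype(float)
    if n_sig:
        arch = planted_archetypes(cfg)
        per_gene = np.arange(n_sig) % cfg.n_profiles
        values[:n_sig] += arch[per_gene][:, None, :]
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)

    flat = values.reshape(G, L * T)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    flat = np.where(sd > 1e-12, (flat - mu) / np.where(sd > 0, sd, 1.0), flat - mu)
    cols = pd.MultiIndex.from_tuples(
        [(l, h) for l in lines for h in hours], names=["cell_line", "hour"]
    )
    df = pd.DataFrame(flat, index=pd.Index(genes, name="gene_id"), columns=cols)
    return TimeCourseExperiment(values=df)


def simulate_sf2(cfg: SimulationConfig, expr: pd.DataFrame) -> pd.Series:
    """SF2 per cell line from the signature genes' baseline expression.

    ``expr`` is genes x cell lines (baseline, emitted scale).  The log
    survival is the mean planted SGLQ response over signature genes,
    perturbed with Gaussian log-scale noise and clipped to (0, 1].
    """
    sig = [g for g in cfg.signature_genes(expr.index) if g in expr.index]
    if not sig:
        raise ConfigurationError("no signature genes available for SF2 generation")
    rng = np.random.default_rng(cfg._seeds()["sf2"])
    E = expr.loc[sig].to_numpy(dtype=float)
    log_sf = (cfg.sglq_alpha * E - cfg.sglq_beta * E**2).mean(axis=0)
    log_sf = log_sf + rng.normal(0.0, cfg.sf2_log_noise_sd, size=log_sf.shape)
    sf2 = np.minimum(np.exp(log_sf), 1.0)
    return pd.Series(sf2, index=expr.columns, name="sf2")


def simulate_network_layers(cfg: SimulationConfig):
    """Mutation, CNA and protein layers over an ER background graph.

    Signature genes are additionally wired into a dense subgraph (edge
    probability ``signature_density``) that must come out connected, and
    their heat means are multiplied by ``heat_elevation``.  The co-expression
    layer is derived from the bulk matrix downstream, not here.
    """
    from .omicsnet import NetworkLayer

    seeds = cfg._seeds()
    rng = np.random.default_rng(seeds["network"])
    genes = cfg.gene_ids
    sig = cfg.signature_genes()
    n = cfg.n_genes
    p = min(cfg.network_mean_degree / max(n - 1, 1), 1.0)
    er = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    G = nx.relabel_nodes(er, dict(enumerate(genes)))
    for u, v in G.edges:
        G.edges[u, v]["weight"] = float(rng.uniform(0.5, 1.0))
    for i, a in enumerate(sig):
        for b in sig[i + 1 :]:
            if rng.random() < cfg.signature_density:
                G.add_edge(a, b, weight=float(rng.uniform(0.75, 1.0)))
    if sig and not nx.is_connected(G.subgraph(sig)):
        raise GenerationError(
            "planted signature subgraph is disconnected; "
            "increase signature_density"
        )

    hrng = np.random.default_rng(seeds["heat"])
    heats = {}
    for kind in ("mutation", "cna"):
        h = hrng.exponential(cfg.heat_scale, size=n)
        h[: cfg.n_signature] = hrng.exponential(
            cfg.heat_scale * cfg.heat_elevation, size=cfg.n_signature
        )
        heats[kind] = pd.Series(h, index=genes, name="heat")
    return [
        NetworkLayer(kind="mutation", graph=G, heat=heats["mutation"]),
        NetworkLayer(kind="cna", graph=G, heat=heats["cna"]),
        NetworkLayer(kind="protein", graph=G),
    ]


def _ground_truth(cfg: SimulationConfig, layers) -> GroundTruth:
    sig = cfg.signature_genes()
    heat = {layer.kind: layer.heat for layer in layers if layer.heat is not None}
    per_gene = np.arange(cfg.n_signature) % max(cfg.n_profiles, 1)
    return GroundTruth(
        signature_genes=sig,
        alpha={g: cfg.sglq_alpha for g in sig},
        beta={g: cfg.sglq_beta for g in sig},
        profile={g: int(per_gene[i]) for i, g in enumerate(sig)},
        mutation_heat={g: float(heat["mutation"][g]) for g in sig},
        cna_heat={g: float(heat["cna"][g]) for g in sig},
    )


def simulate_bundle(cfg: SimulationConfig) -> tuple[rio.Bundle, GroundTruth]:
    """Generate every pipeline input in memory."""
    expr = simulate_timecourse(cfg)
    sf2 = simulate_sf2(cfg, expr.baseline()) if cfg.n_signature else _null_sf2(cfg)
    layers = simulate_network_layers(cfg)
    truth = _ground_truth(cfg, layers)
    edges = nx.to_pandas_edgelist(
        layers[-1].graph, source="gene_a", target="gene_b"
    )
    edges = edges.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    heats = {l.kind: l.heat for l in layers if l.heat is not None}
    decoy_rng = np.random.default_rng(cfg._seeds()["network"].spawn(1)[0])
    gene_sets = {"planted_signature": list(truth.signature_genes)}
    for i in range(1, 6):
        gene_sets[f"decoy_set_{i}"] = sorted(
            decoy_rng.choice(cfg.gene_ids, size=25, replace=False)
        )
    bundle = rio.Bundle(
        expression=expr,
        sf2=sf2,
        heats=heats,
        edges=edges,
        gene_sets=gene_sets,
        truth=json.loads(truth.to_json()),
    )
    return bundle, truth


def _null_sf2(cfg: SimulationConfig) -> pd.Series:
    """SF2 unrelated to any gene, for null bundles without planted genes."""
    rng = np.random.default_rng(cfg._seeds()["sf2"])
    sf2 = np.minimum(np.exp(rng.normal(-0.5, 0.2, len(cfg.cell_lines))), 1.0)
    return pd.Series(sf2, index=list(cfg.cell_lines), name="sf2")


def write_fixture_bundle(cfg: SimulationConfig, directory) -> dict:
    """Emit the full bundle as plain-text files and return a manifest.

    Two calls with the same config (and seed) produce byte-identical files;
    the manifest records a SHA-256 checksum per file.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle, truth = simulate_bundle(cfg)
    try:
        rio.write_expression(bundle.expression, d / rio.BUNDLE_FILES["expression"])
        rio.write_sf2(bundle.sf2, d / rio.BUNDLE_FILES["sf2"])
        for kind in ("mutation", "cna"):
            rio.write_heat(bundle.heats[kind], d / rio.BUNDLE_FILES[kind])
        rio.write_edges(bundle.edges, d / rio.BUNDLE_FILES["edges"])
        rio.write_gmt(bundle.gene_sets, d / rio.BUNDLE_FILES["gene_sets"])
        (d / rio.BUNDLE_FILES["truth"]).write_text(truth.to_json())
    except OSError as exc:
        raise IOError(f"{directory}: {exc}") from exc
    manifest = {
        "config": dataclasses.asdict(cfg),
        "files": {
            key: {"path": fname, "sha256": rio.sha256_of(d / fname)}
            for key, fname in rio.BUNDLE_FILES.items()
        },
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
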