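"""Two-group RNA-seq count simulation under a negative-binomial model.

Each simulated experiment compares two groups of ``n_per_group`` libraries
over ``n_genes`` genes.  A configured proportion of genes is differentially
expressed (DE); each DE gene gets a direction indicator ``d in {+1, -1}``
and a fold change

    fc = (rho + rho_star) ** d,

where ``rho`` is a gamma(shape, rate) draw and ``rho_star`` is the
fold-change lower bound, so up-regulated genes satisfy ``fc >= rho_star``
and down-regulated ones ``fc <= 1 / rho_star``.  Non-DE genes have
``d = 0`` and ``fc = 1``.  Group-1 counts are NB(mu, phi) from the gene
panel; group-2 counts are NB(mu * fc, phi) with the dispersion shared
between groups.  Library sizes are equal by construction.

Seven preset scenario designs (I-VII) varying sample size, DE proportion,
up/down ratio, fold-change lower bound and depth lower bound are shipped
as YAML files and exposed through :func:`scenario_config`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import NBGeneParams, PanelSpec, make_standin_panel, truncate_panel_at_depth

__all__ = [
    "ScenarioConfig",
    "TruthTable",
    "SimulatedExperiment",
    "scenario_config",
    "scenario_names",
    "assign_de_status",
    "draw_fold_changes",
    "simulate_counts",
    "simulate_experiment",
    "simulate_scenario",
]

#: Default gamma law for the fold-change magnitude rho.
GAMMA_SHAPE = 0.87
GAMMA_RATE = 1.36


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation design: sample size, DE structure, and bounds."""

    name: str
    n_per_group: int
    prop_de: float
    up_down_ratio: tuple[float, float] = (1.0, 1.0)
    fc_lower_bound: float = 1.5
    depth_lower_bound: float = 5.0
    n_genes: int = 10_000
    n_datasets: int = 30
    gamma_shape: float = GAMMA_SHAPE
    gamma_rate: float = GAMMA_RATE
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.prop_de < 1:
            raise ValueError("prop_de must lie strictly between 0 and 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.fc_lower_bound < 1:
            raise ValueError("fc_lower_bound must be >= 1")
        if self.n_genes < 1 or self.n_datasets < 1:
            raise ValueError("n_genes and n_datasets must be >= 1")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma shape and rate must be > 0")
        up, down = self.up_down_ratio
        if up < 0 or down < 0 or up + down <= 0:
            raise ValueError("up_down_ratio parts must be >= 0 and not both 0")

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["up_down_ratio"] = list(self.up_down_ratio)
        return d


def _load_presets() -> dict[str, dict]:
    presets = {}
    base = resources.files("debench") / "data" / "scenarios"
    for entry in sorted(base.iterdir()):
        if entry.name.endswith(".yaml"):
            raw = yaml.safe_load(entry.read_text())
            presets[raw["name"]] = raw
    return presets


_PRESETS: dict[str, dict] | None = None


_ROMAN_ORDER = ["I", "II", "III", "IV", "V", "VI", "VII"]


def scenario_names() -> list[str]:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    known = [n for n in _ROMAN_ORDER if n in _PRESETS]
    return known + sorted(set(_PRESETS) - set(known))


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a named preset (I-VII).

    Keyword overrides (e.g. ``n_genes=1000, seed=7``) replace preset
    fields.
    """
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    if name not in _PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; valid presets: {sorted(_PRESETS)}"
        )
    raw = dict(_PRESETS[name])
    raw["up_down_ratio"] = tuple(raw["up_down_ratio"])
    raw.update(overrides)
    return ScenarioConfig(**raw)


@dataclass(frozen=True)
class TruthTable:
    """Per-gene simulation ground truth.

    ``d`` is the direction indicator (+1 up, -1 down, 0 non-DE), ``rho``
    the gamma magnitude draw (NaN where ``d = 0``) and ``fc`` the realized
    fold change, exactly 1 for non-DE genes.
    """

    d: np.ndarray
    rho: np.ndarray
    fc: np.ndarray

    @property
    def is_de(self) -> np.ndarray:
        return self.d != 0

    @property
    def n_de(self) -> int:
        return int(np.count_nonzero(self.d))

    def to_frame(self, gene_id=None) -> pd.DataFrame:
        if gene_id is None:
            gene_id = [f"gene_{i + 1}" for i in range(len(self.d))]
        return pd.DataFrame({"gene_id": gene_id, "d": self.d, "fc": self.fc})


@dataclass(frozen=True)
class SimulatedExperiment:
    """Counts, design and ground truth of one simulated dataset."""

    counts: np.ndarray
    group: np.ndarray
    truth: TruthTable
    panel: NBGeneParams
    config: ScenarioConfig
    dataset_index: int = 0

    @property
    def sample_names(self) -> list[str]:
        return [f"s{g}_{j + 1}" for j, g in enumerate(self.group)]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.panel.gene_id, columns=self.sample_names
        )


def assign_de_status(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the per-gene direction vector d for one dataset.

    Exactly ``round(prop_de * n_genes)`` genes are DE; among them the
    up-regulated count is ``round(n_de * up / (up + down))`` and the rest
    are down-regulated.  Positions are uniformly random.
    """
    G = config.n_genes
    n_de = int(round(config.prop_de * G))
    if n_de < 1:
        raise ValueError("prop_de * n_genes < 1: no DE gene to place")
    up_w, down_w = config.up_down_ratio
    n_up = int(round(n_de * up_w / (up_w + down_w)))
    n_down = n_de - n_up
    d = np.zeros(G, dtype=np.int8)
    pos = rng.choice(G, size=n_de, replace=False)
    d[pos[:n_up]] = 1
    d[pos[n_up:]] = -1
    return d


def draw_fold_changes(
    d: np.ndarray, config: ScenarioConfig, rng: np.random.Generator
) -> TruthTable:
    """Draw gamma fold-change magnitudes and realize fc = (rho + rho*)^d."""
    d = np.asarray(d)
    if not np.isin(d, (-1, 0, 1)).all():
        raise ValueError("direction vector may only contain -1, 0, +1")
    G = len(d)
    rho = np.full(G, np.nan)
    fc = np.ones(G)
    de = d != 0
    rho[de] = rng.gamma(shape=config.gamma_shape, scale=1.0 / config.gamma_rate,
                        size=int(de.sum()))
    base = rho[de] + config.fc_lower_bound
    fc[de] = np.where(d[de] > 0, base, 1.0 / base)
    return TruthTable(d=d.astype(np.int8), rho=rho, fc=fc)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray,
             size: tuple[int, ...]) -> np.ndarray:
    """NB2 variates with per-gene mean and dispersion, Poisson when phi=0."""
    mean = np.broadcast_to(mean, size)
    phi = np.broadcast_to(phi, size)
    out = np.empty(size, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    panel: NBGeneParams,
    truth: TruthTable,
    config: ScenarioConfig,
    rng: np.random.Generator,
    dataset_index: int = 0,
) -> SimulatedExperiment:
    """Draw the gene x sample count matrix for one dataset.

    Group-1 samples are NB(mu, phi); group-2 samples are NB(mu * fc, phi).
    """
    if len(panel) != len(truth.d):
        raise ValueError("panel and truth must cover the same genes")
    n = config.n_per_group
    G = len(panel)
    mu1 = panel.mu[:, None]
    mu2 = (panel.mu * truth.fc)[:, None]
    phi = panel.phi[:, None]
    counts = np.concatenate(
        [
            _nb_draw(rng, mu1, phi, (G, n)),
            _nb_draw(rng, mu2, phi, (G, n)),
        ],
        axis=1,
    )
    group = np.repeat([1, 2], n)
    return SimulatedExperiment(
        counts=counts, group=group, truth=truth, panel=panel,
        config=config, dataset_index=dataset_index,
    )


def simulate_experiment(
    panel: NBGeneParams,
    config: ScenarioConfig,
    rng: np.random.Generator,
    dataset_index: int = 0,
) -> SimulatedExperiment:
    """DE assignment, fold-change draw and count draw for one dataset."""
    d = assign_de_status(config, rng)
    truth = draw_fold_changes(d, config, rng)
    return simulate_counts(panel, truth, config, rng, dataset_index)


def simulate_scenario(
    config: ScenarioConfig,
    panel_spec: PanelSpec | None = None,
    panel: NBGeneParams | None = None,
) -> list[SimulatedExperiment]:
    """Simulate ``config.n_datasets`` independent replicate datasets.

    The gene panel is fixed across replicates (it plays the role of a
    set of parameters estimated once from real data); DE positions and
    fold changes are redrawn for every dataset.  All randomness derives
    deterministically from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    panel_seq, *dataset_seqs = root.spawn(config.n_datasets + 1)
    if panel is None:
        spec = panel_spec or PanelSpec(n_genes=config.n_genes)
        if spec.n_genes != config.n_genes:
            spec = dataclasses.replace(spec, n_genes=config.n_genes)
        seeds = panel_seq.generate_state(2)
        spec = dataclasses.replace(spec, seed=int(seeds[0]))
        panel = make_standin_panel(spec)
        panel = truncate_panel_at_depth(
            panel, config.depth_lower_bound, spec=spec, seed=int(seeds[1])
        )
    elif len(panel) != config.n_genes:
        raise ValueError("supplied panel size differs from config.n_genes")
    elif panel.mu.min() < config.depth_lower_bound:
        panel = truncate_panel_at_depth(
            panel, config.depth_lower_bound,
            seed=int(panel_seq.generate_state(1)[0]),
        )
    return [
        simulate_experiment(panel, config, np.random.default_rng(seq), k)
        for k, seq in enumerate(dataset_seqs)
    ]


def write_experiment(exp: SimulatedExperiment, outdir, prefix: str | None = None) -> dict:
    """Write counts/truth TSVs and a JSON sidecar; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if prefix is None:
        prefix = f"{exp.config.name}_rep{exp.dataset_index + 1}"
    paths = {
        "counts": outdir / f"{prefix}_counts.tsv",
        "truth": outdir / f"{prefix}_truth.tsv",
        "design": outdir / f"{prefix}_design.tsv",
        "sidecar": outdir / f"{prefix}_run.json",
    }
    exp.counts_frame().to_csv(paths["counts"], sep="\t", index_label="gene_id")
    exp.truth.to_frame(exp.panel.gene_id).to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame({"sample": exp.sample_names, "group": exp.group}).to_csv(
        paths["design"], sep="\t", index=False
    )
    sidecar = {
        "config": exp.config.to_dict(),
        "dataset_index": exp.dataset_index,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
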