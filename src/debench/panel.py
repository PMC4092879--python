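"""Per-gene negative-binomial parameter panels.

A panel holds, for each gene, the negative-binomial mean ``mu`` (expected
read count per library) and dispersion ``phi`` under the NB2 parameterization

    Var(Y) = mu + phi * mu**2,

so ``phi -> 0`` recovers the Poisson.  Panels are the raw material of the
count simulator: they can be estimated from a real count matrix by the
method of moments, or generated synthetically as a documented stand-in for
parameters estimated from a large tumour/normal compendium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NBGeneParams",
    "PanelSpec",
    "estimate_nb_params",
    "make_standin_panel",
    "truncate_panel_at_depth",
]


@dataclass(frozen=True)
class NBGeneParams:
    """A per-gene NB(mu, phi) parameter panel.

    Parameters
    ----------
    gene_id : array of str
        Unique gene identifiers.
    mu : array of float
        Per-gene NB means, all ``>= 0``.
    phi : array of float
        Per-gene NB2 dispersions, all ``>= 0``.
    """

    gene_id: np.ndarray
    mu: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        gene_id = np.asarray(self.gene_id, dtype=object)
        mu = np.asarray(self.mu, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if not (len(gene_id) == len(mu) == len(phi)):
            raise ValueError("gene_id, mu and phi must have equal length")
        if len(gene_id) < 1:
            raise ValueError("panel must contain at least one gene")
        if len(set(gene_id)) != len(gene_id):
            raise ValueError("gene_ids must be unique")
        if np.any(mu < 0) or not np.all(np.isfinite(mu)):
            raise ValueError("mu must be finite and >= 0 for every gene")
        if np.any(phi < 0) or not np.all(np.isfinite(phi)):
            raise ValueError("phi must be finite and >= 0 for every gene")
        object.__setattr__(self, "gene_id", gene_id)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "phi", phi)

    def __len__(self) -> int:
        return len(self.gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_id, "mu": self.mu, "phi": self.phi}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NBGeneParams":
        return cls(
            gene_id=df["gene_id"].to_numpy(dtype=object),
            mu=df["mu"].to_numpy(dtype=float),
            phi=df["phi"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class PanelSpec:
    """Configuration of a synthetic stand-in panel.

    Means are drawn from a log-normal law (``mu_log_mean``/``mu_log_sd`` on
    the natural-log scale) and dispersions from a gamma law
    (``phi_shape``/``phi_scale``).  Defaults emulate deep bulk RNA-seq
    libraries over a genome-wide gene set: median mu = exp(mu_log_mean)
    around 300 counts, median phi around 0.33 (biological CV ~ 0.57),
    in the range typical of heterogeneous human tissue.
    """

    n_genes: int = 10_000
    mu_log_mean: float = float(np.log(300.0))
    mu_log_sd: float = 1.5
    phi_shape: float = 2.0
    phi_scale: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.mu_log_sd < 0:
            raise ValueError("mu_log_sd must be >= 0")
        if self.phi_shape <= 0 or self.phi_scale < 0:
            raise ValueError("phi_shape must be > 0 and phi_scale >= 0")


def _library_size_normalize(counts: np.ndarray) -> np.ndarray:
    """Scale each sample to the mean library size (total-count scaling)."""
    totals = counts.sum(axis=0, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("every sample must have a positive total count")
    return counts * (totals.mean() / totals)


def estimate_nb_params(
    counts: pd.DataFrame | np.ndarray,
    group_labels,
    gene_id=None,
) -> NBGeneParams:
    """Method-of-moments NB parameter estimates from a count matrix.

    Estimates are computed within the reference group (the first label in
    order of appearance) after total-count library-size normalization:
    ``mu_hat`` is the sample mean and ``phi_hat = max(0, (s2 - mu) / mu^2)``
    with the unbiased sample variance ``s2``.  Genes with ``mu_hat = 0``
    get ``phi_hat = 0``.

    Parameters
    ----------
    counts : DataFrame (genes x samples) or 2-D integer array
        Non-negative integer read counts.  If a DataFrame, the index
        provides gene identifiers.
    group_labels : sequence
        Per-sample labels; the first label in order of appearance marks
        the reference group, which must contain at least two samples.
    """
    if isinstance(counts, pd.DataFrame):
        if gene_id is None:
            gene_id = counts.index.to_numpy(dtype=object)
        mat = counts.to_numpy()
    else:
        mat = np.asarray(counts)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D gene x sample matrix")
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat, np.round(mat)):
            raise ValueError("counts must be integers")
        mat = np.round(mat).astype(np.int64)
    labels = np.asarray(list(group_labels))
    if len(labels) != mat.shape[1]:
        raise ValueError("one group label per sample is required")
    ref = labels[0]
    ref_cols = labels == ref
    if ref_cols.sum() < 2:
        raise ValueError(
            "reference group needs >= 2 samples to estimate a variance"
        )
    if gene_id is None:
        gene_id = np.array([f"g{i}" for i in range(mat.shape[0])], dtype=object)

    norm = _library_size_normalize(mat.astype(float))[:, ref_cols]
    mu = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (s2 - mu) / mu**2
    phi = np.where(mu > 0, np.maximum(phi, 0.0), 0.0)
    return NBGeneParams(gene_id=np.asarray(gene_id, dtype=object), mu=mu, phi=phi)


def _draw_panel_values(spec: PanelSpec, n: int, rng: np.random.Generator):
    mu = rng.lognormal(mean=spec.mu_log_mean, sigma=spec.mu_log_sd, size=n)
    if spec.phi_scale == 0:
        phi = np.zeros(n)
    else:
        phi = rng.gamma(shape=spec.phi_shape, scale=spec.phi_scale, size=n)
    return mu, phi


def make_standin_panel(spec: PanelSpec) -> NBGeneParams:
    """Generate a synthetic NB parameter panel from a :class:`PanelSpec`.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mu, phi = _draw_panel_values(spec, spec.n_genes, rng)
    gene_id = np.array([f"gene_{i + 1}" for i in range(spec.n_genes)], dtype=object)
    return NBGeneParams(gene_id=gene_id, mu=mu, phi=phi)


def truncate_panel_at_depth(
    panel: NBGeneParams,
    depth_lower_bound: float,
    spec: PanelSpec | None = None,
    seed: int | None = None,
    max_attempts: int = 1000,
) -> NBGeneParams:
    """Enforce a lower bound on every per-gene mean by resampling.

    Genes with ``mu < depth_lower_bound`` are replaced: if ``spec`` is
    given, replacements are redrawn from its mean/dispersion laws until
    they clear the bound; otherwise they are resampled with replacement
    from the panel's own genes already above the bound.  Panel size and
    gene identifiers are preserved; the operation is idempotent.
    """
    if depth_lower_bound < 0:
        raise ValueError("depth_lower_bound must be >= 0")
    below = panel.mu < depth_lower_bound
    if not below.any():
        return panel
    rng = np.random.default_rng(seed)
    mu = panel.mu.copy()
    phi = panel.phi.copy()
    idx = np.flatnonzero(below)
    if spec is not None:
        for _ in range(max_attempts):
            new_mu, new_phi = _draw_panel_values(spec, len(idx), rng)
            ok = new_mu >= depth_lower_bound
            mu[idx[ok]] = new_mu[ok]
            phi[idx[ok]] = new_phi[ok]
            idx = idx[~ok]
            if len(idx) == 0:
                break
        else:
            raise RuntimeError(
                f"could not resample {len(idx)} means above "
                f"{depth_lower_bound} in {max_attempts} attempts"
            )
    else:
        donors = np.flatnonzero(~below)
        if len(donors) == 0:
            raise RuntimeError(
                "no panel gene clears the depth bound; cannot resample"
            )
        pick = rng.choice(donors, size=len(idx), replace=True)
        mu[idx] = panel.mu[pick]
        phi[idx] = panel.phi[pick]
    return NBGeneParams(gene_id=panel.gene_id.copy(), mu=mu, phi=phi)
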