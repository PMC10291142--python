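"""Synthetic expression data with known, approximately balanced ground-truth fluxes.

The generator works in three steps:

1. ``flux_mode_basis`` finds a set of sparse, non-negative *flux modes* of
   the factor graph — balanced unit flows from boundary sources to sinks
   (including internal cycles needed to balance multi-substrate modules).
   On a simple chain or diamond these are exactly the 0/1 source-to-sink
   path indicator vectors.
2. ``sample_balanced_fluxes`` draws per-sample positive loads on those
   modes (log-normal, right-skewed like real flux magnitudes) so that
   every intermediate metabolite balances exactly, then optionally adds a
   small truncated Gaussian slack per module.
3. ``expression_from_flux`` emits log(FPKM+1)-scale expression for each
   module's genes through a monotone noisy link
   ``expr = log(1 + w * flux) + eps``, the generative counterpart of the
   assumption that enzyme transcript levels are a latent monotone function
   of reaction rates.

``make_two_group_study`` composes the three into a tumor-vs-normal study
with chosen per-module flux fold-changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .containers import ExpressionMatrix
from .errors import GenerationError, ParameterError
from .network import FactorGraph, incidence_matrix

logger = logging.getLogger(__name__)


@dataclass
class LinkParameters:
    """Parameters of the gene <- flux link used by the generator.

    ``weights`` is a gene x module table of strictly positive weights
    (zero marks "gene not linked to module"); the link family is
    log1p-linear: ``expr_g = log(1 + sum_m w_{g,m} flux_m) + eps``.
    """

    weights: pd.DataFrame
    noise_sd: float
    family: str = "log1p-linear"


@dataclass
class SyntheticDataset:
    """Expression + ground truth produced by :func:`make_two_group_study`."""

    expression: ExpressionMatrix
    true_flux: pd.DataFrame          # sample x module
    link: LinkParameters
    group_labels: pd.Series          # sample -> {"tumor", "normal"}
    perturbed_modules: list[tuple[str, float]] = field(default_factory=list)


def flux_mode_basis(graph: FactorGraph, tol: float = 1e-9) -> pd.DataFrame:
    """Non-negative balanced flux modes of the graph (mode x module).

    For each module m a minimum-total-flux LP is solved over
    ``{f >= 0 : S f = 0, f_m = 1}`` with S the signed intermediate
    incidence matrix; vertices of that LP are sparse balanced flows
    through m.  Duplicates are collapsed.  Modules for which no balanced
    flow exists are logged and left uncovered; if no module admits one,
    generation is impossible and an error is raised.
    """
    S = incidence_matrix(graph).to_numpy()
    mods = graph.module_ids
    M = len(mods)
    modes: list[np.ndarray] = []
    seen: set[tuple] = set()
    uncovered: list[str] = []
    for m in range(M):
        a_eq = np.vstack([S, np.eye(M)[m]])
        b_eq = np.zeros(S.shape[0] + 1)
        b_eq[-1] = 1.0
        res = linprog(c=np.ones(M), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
        if not res.success:
            uncovered.append(mods[m])
            continue
        mode = np.where(res.x < tol, 0.0, res.x)
        key = tuple(np.round(mode, 6))
        if key not in seen:
            seen.add(key)
            modes.append(mode)
    if not modes:
        raise GenerationError(
            "no balanced source-to-sink flow exists in this graph "
            "(no directed source->sink path)"
        )
    if uncovered:
        logger.warning("modules with no balanced flow (left uncovered): %s", uncovered)
    basis = pd.DataFrame(np.vstack(modes), columns=mods)
    basis.index = [f"mode_{i}" for i in range(len(basis))]
    return basis


def sample_balanced_fluxes(
    graph: FactorGraph,
    n_samples: int,
    seed: int,
    slack_sd: float = 0.0,
    load_meanlog: float = 0.0,
    load_sdlog: float = 0.5,
    basis: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw a sample x module matrix of non-negative, balanced fluxes.

    Each sample is a log-normal(meanlog, sdlog) positive combination of the
    graph's flux modes; with ``slack_sd=0`` every intermediate balances
    exactly.  A per-module Gaussian slack of sd ``slack_sd`` is then added
    and the result truncated at zero.  Deterministic given ``seed``.
    """
    if n_samples <= 0:
        raise ParameterError("n_samples must be positive")
    if slack_sd < 0:
        raise ParameterError("slack_sd must be non-negative")
    if basis is None:
        basis = flux_mode_basis(graph)
    rng = np.random.default_rng(seed)
    loads = rng.lognormal(mean=load_meanlog, sigma=load_sdlog, size=(n_samples, len(basis)))
    flux = loads @ basis.to_numpy()
    if slack_sd > 0:
        flux = flux + rng.normal(0.0, slack_sd, size=flux.shape)
    flux = np.maximum(flux, 0.0)
    return pd.DataFrame(
        flux, index=[f"S{j}" for j in range(n_samples)], columns=graph.module_ids
    )


def expression_from_flux(
    true_flux: pd.DataFrame,
    graph: FactorGraph,
    genes_per_module: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    weight_sdlog: float = 0.25,
) -> tuple[ExpressionMatrix, LinkParameters]:
    """Emit log(FPKM+1)-scale expression for the graph's genes from true fluxes.

    Up to ``genes_per_module`` of each module's declared genes are used; a
    gene shared by several modules responds to the weighted sum of their
    fluxes.  Each gene gets ``expr = log(1 + sum_m w_{g,m} flux_m) + eps``
    with ``w`` log-normal (``weight_sdlog=0`` gives w=1 exactly) and
    ``eps ~ N(0, noise_sd)``, clipped at zero.  Deterministic given ``seed``.
    """
    if genes_per_module <= 0:
        raise ParameterError("genes_per_module must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    flux = true_flux.reindex(columns=graph.module_ids)
    if flux.isna().any().any():
        raise ParameterError("true_flux columns do not align to the graph's modules")
    if (flux.to_numpy() < 0).any():
        raise ParameterError("true_flux must be non-negative (generator contract)")

    rng = np.random.default_rng(seed)
    gene_modules: dict[str, list[str]] = {}
    for mod in graph.modules.values():
        for g in mod.genes[:genes_per_module]:
            gene_modules.setdefault(g, []).append(mod.id)
    genes = list(gene_modules)
    weights = pd.DataFrame(0.0, index=genes, columns=graph.module_ids)
    for g, mods in gene_modules.items():
        for m in mods:
            weights.loc[g, m] = rng.lognormal(0.0, weight_sdlog) if weight_sdlog > 0 else 1.0

    signal = weights.to_numpy() @ flux.to_numpy().T      # gene x sample
    expr = np.log1p(signal)
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    expr = np.maximum(expr, 0.0)
    values = pd.DataFrame(expr, index=genes, columns=flux.index)
    return ExpressionMatrix(values), LinkParameters(weights=weights, noise_sd=noise_sd)


def make_two_group_study(
    graph: FactorGraph,
    n_per_group: int,
    perturbed_modules: list[tuple[str, float]] | None = None,
    seed: int = 0,
    genes_per_module: int = 3,
    noise_sd: float = 0.1,
    slack_sd: float = 0.0,
    load_meanlog: float = 0.0,
    load_sdlog: float = 0.5,
    cancer_type: str = "SYN",
) -> SyntheticDataset:
    """Tumor-vs-normal synthetic study with chosen per-module flux fold-changes.

    Tumor-group loads of every flux mode passing through a perturbed module
    are multiplied by that module's fold-change, so the perturbed module's
    expected flux changes by exactly ``fold_change``; modules sharing a mode
    with it shift proportionally (balance is preserved by construction),
    while modes avoiding it are untouched.  With an empty perturbation list
    the two groups are exchangeable.
    """
    perturbed_modules = list(perturbed_modules or [])
    for mid, fold in perturbed_modules:
        if mid not in graph.modules:
            raise ParameterError(f"perturbed module {mid!r} not in graph")
        if fold <= 0:
            raise ParameterError(f"fold_change for {mid!r} must be > 0, got {fold}")

    basis = flux_mode_basis(graph)
    rng = np.random.default_rng(seed)
    n = n_per_group
    loads = rng.lognormal(load_meanlog, load_sdlog, size=(2 * n, len(basis)))

    scale = np.ones(len(basis))
    b = basis.to_numpy()
    for mid, fold in perturbed_modules:
        col = basis.columns.get_loc(mid)
        scale = scale * np.where(b[:, col] > 1e-9, fold, 1.0)
    loads[:n] *= scale  # first block = tumor group

    flux = loads @ b
    if slack_sd > 0:
        flux = flux + rng.normal(0.0, slack_sd, size=flux.shape)
    flux = np.maximum(flux, 0.0)

    samples = [f"T{j}" for j in range(n)] + [f"N{j}" for j in range(n)]
    true_flux = pd.DataFrame(flux, index=samples, columns=graph.module_ids)
    expression, link = expression_from_flux(
        true_flux, graph, genes_per_module=genes_per_module,
        noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1)),
    )
    labels = pd.Series(["tumor"] * n + ["normal"] * n, index=samples, name="status")
    expression.metadata = pd.DataFrame(
        {"status": labels, "cancer_type": cancer_type, "stage": pd.NA}, index=samples
    )
    return SyntheticDataset(
        expression=expression,
        true_flux=true_flux,
        link=link,
        group_labels=labels,
        perturbed_modules=perturbed_modules,
    )
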