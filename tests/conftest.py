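import numpy as np
import pandas as pd
import pytest

from fluxcentral.containers import ExpressionMatrix
from fluxcentral.network import FactorGraph, Metabolite, ReactionModule


def _module(mid, inputs, outputs, n_genes=3):
    return ReactionModule(
        id=mid, name=mid, inputs=tuple(inputs), outputs=tuple(outputs),
        genes=tuple(f"{mid}_g{k}" for k in range(n_genes)),
    )


def make_chain(n_genes=3) -> FactorGraph:
    """Glc -> M1 -> pyr_c -> M2 -> cit_m -> M3 -> CO2 (two intermediates)."""
    mets = {
        "Glc": Metabolite("Glc", "glucose", "extracellular", "end"),
        "pyr_c": Metabolite("pyr_c", "pyruvate", "cytosol", "intermediate"),
        "cit_m": Metabolite("cit_m", "citrate", "mitochondria", "intermediate"),
        "CO2": Metabolite("CO2", "CO2", "mitochondria", "end"),
    }
    mods = {
        "M1": _module("M1", ["Glc"], ["pyr_c"], n_genes),
        "M2": _module("M2", ["pyr_c"], ["cit_m"], n_genes),
        "M3": _module("M3", ["cit_m"], ["CO2"], n_genes),
    }
    return FactorGraph(mets, mods)


def make_diamond(n_genes=3) -> FactorGraph:
    """One source splitting into two parallel paths that rejoin before the sink."""
    mets = {
        "src": Metabolite("src", "source", "extracellular", "end"),
        "A": Metabolite("A", "A", "cytosol", "intermediate"),
        "B": Metabolite("B", "B", "cytosol", "intermediate"),
        "snk": Metabolite("snk", "sink", "extracellular", "end"),
    }
    mods = {
        "M1": _module("M1", ["src"], ["A"], n_genes),
        "M2": _module("M2", ["A"], ["B"], n_genes),
        "M3": _module("M3", ["A"], ["B"], n_genes),
        "M4": _module("M4", ["B"], ["snk"], n_genes),
    }
    return FactorGraph(mets, mods)


@pytest.fixture
def chain_graph():
    return make_chain()


@pytest.fixture
def diamond_graph():
    return make_diamond()


@pytest.fixture(scope="session")
def central_graph():
    from fluxcentral.network import central_metabolism_fixture
    return central_metabolism_fixture()


def identity_expression(flux: pd.DataFrame, graph: FactorGraph) -> ExpressionMatrix:
    """One gene per module, expression equal to the flux itself (identity link)."""
    rows = {}
    for mid in graph.module_ids:
        rows[graph.modules[mid].genes[0]] = flux[mid].to_numpy()
    values = pd.DataFrame(rows, index=flux.index).T
    return ExpressionMatrix(values)
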