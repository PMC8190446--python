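import numpy as np
import pandas as pd
import pytest

from mitocurse import PanelDesign, SimulationConfig, drosophila_panel, simulate_panel


@pytest.fixture(scope="session")
def panel_design():
    """The 9 x 9 design with the one inviable cell (80 genotypes)."""
    return drosophila_panel()


@pytest.fixture(scope="session")
def default_panel(panel_design):
    """One seeded panel simulated under the default (study-like) conditions."""
    return simulate_panel(SimulationConfig(design=panel_design, seed=20210313))


@pytest.fixture
def small_design():
    return PanelDesign.fully_crossed(list("ABC"))


def make_table(records):
    """Phenotype table from (nuc, mito, sex, trait) tuples."""
    rows = [
        {
            "individual_id": f"r{i}",
            "nuc": n,
            "mito": m,
            "sex": s,
            "replicate": "v1",
            "trait": t,
        }
        for i, (n, m, s, t) in enumerate(records)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def table_factory():
    return make_table


def balanced_anova_oracle(table, factors):
    """Closed-form sequential SS for a *balanced complete* factorial.

    Uses the orthogonal cell-mean decomposition (inclusion-exclusion of
    marginal means); on balanced designs this equals sequential SS in any
    order.  Returns {term_name: ss} plus 'residual'.
    """
    from itertools import combinations

    y = table["trait"].to_numpy(dtype=float)
    grand = y.mean()
    out = {}
    margins = {}
    for k in range(1, len(factors) + 1):
        for combo in combinations(factors, k):
            cell = table.groupby(list(combo))["trait"].transform("mean").to_numpy()
            # inclusion-exclusion: subtract all lower-order components
            comp = cell - grand
            for sub_k in range(1, k):
                for sub in combinations(combo, sub_k):
                    comp = comp - margins[sub]
            margins[combo] = comp
            out[":".join(combo)] = float(np.sum(comp**2))
    full_cell = table.groupby(list(factors))["trait"].transform("mean").to_numpy()
    out["residual"] = float(np.sum((y - full_cell) ** 2))
    return out
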