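"""Median substitution vs iterative forest imputation on masked cells.

Depth is masked at 30% and both imputers fill it back; masked-cell RMSE is
scored against the truth.  When depth is strongly coupled to width
(copula correlation 0.9) the forest imputer wins decisively; with fully
independent gradients it offers no material advantage.
"""

import numpy as np

from phytoranges import (
    apply_missingness,
    default_gradient_spec,
    generate_sites,
    impute_iterative_forest,
    impute_median_mode,
)


def masked_cell_rmse(rho: float, seed: int = 41) -> tuple[float, float]:
    spec = default_gradient_spec()
    spec.correlation.loc[:, :] = np.eye(6)
    spec.correlation.loc["width", "depth"] = rho
    spec.correlation.loc["depth", "width"] = rho
    spec.substrate_size_coupling = 1e-9  # keep substrate uninformative
    sites = generate_sites(spec, 400, seed)
    truth = sites.data["depth"].to_numpy().copy()
    masked = apply_missingness(sites, {"depth": 0.3}, seed + 1)
    miss = masked.data["depth"].isna().to_numpy()
    med, _ = impute_median_mode(masked)
    fo, rep = impute_iterative_forest(masked, ntree=50, seed=seed + 2)

    def rmse(table):
        return float(np.sqrt(np.mean((table.data["depth"].to_numpy()[miss] - truth[miss]) ** 2)))

    print(f"rho={rho}: median RMSE {rmse(med):.3f} m, forest RMSE {rmse(fo):.3f} m "
          f"({(rmse(med) - rmse(fo)) / rmse(med):+.0%} improvement, "
          f"{rep.iterations} sweeps)")


masked_cell_rmse(rho=0.9)
masked_cell_rmse(rho=0.0)

# The contrast explains why, on weakly structured survey data, the simple
# median track can perform as well as the iterative imputer at model level.
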