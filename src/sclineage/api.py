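"""Model/Results interface for whole-dataset lineage reconstruction.

:class:`CellLineageModel` is constructed from per-site read observations (a
sites JSON file or :class:`~sclineage.sites.SiteObservation` objects);
``fit()`` computes the per-site distance matrices (optionally in parallel —
per-site computations are independent, so the result is identical for any
worker count), aggregates them, reconstructs the neighbor-joining tree
rooted at the bulk, and optionally adds site-bootstrap trees with transfer
bootstrap expectation supports.  The returned
:class:`CellLineageResults` carries the distance matrix, the tree(s), the
parameter estimates and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from joblib import Parallel, delayed

from sclineage.estimate import MHConfig, MHResult, data_log_likelihood, mh_sample
from sclineage.metrics import tbe_supports
from sclineage.model import (
    DistanceMatrix,
    ModelParameters,
    PreparedSite,
    aggregate_distances,
    prepare_site,
    site_distance_matrix,
)
from sclineage.sites import SiteObservation, sites_from_json
from sclineage.tree import bootstrap_trees, neighbor_joining, reroot_at_bulk


class CellLineageModel:
    """Distance-based lineage-tree model over cells + bulk.

    Parameters
    ----------
    sites
        Per-site read observations (all with the same cell count).
    cell_labels
        Taxon labels for the cells; default ``cell0 .. cell{C-1}``.  The
        bulk taxon is always labelled ``bulk`` and placed last.
    params
        Model parameters/hyperparameters; default :class:`ModelParameters`.
    max_coverage
        Optional per-cell read cap per site (bounds the cubic DP cost on
        unusually deep sites); ``None`` uses every read.
    """

    def __init__(
        self,
        sites: list[SiteObservation],
        cell_labels: list[str] | None = None,
        params: ModelParameters | None = None,
        max_coverage: int | None = None,
    ):
        if not sites:
            raise ValueError("the model needs at least one site observation")
        self.sites = list(sites)
        self.n_cells = sites[0].n_cells
        if any(s.n_cells != self.n_cells for s in sites):
            raise ValueError("all sites must cover the same cells")
        if cell_labels is None:
            cell_labels = [f"cell{i}" for i in range(self.n_cells)]
        if len(cell_labels) != self.n_cells:
            raise ValueError("one label per cell required")
        self.labels = list(cell_labels) + ["bulk"]
        self.params = params or ModelParameters()
        self.max_coverage = max_coverage
        self._prepared: list[PreparedSite] | None = None

    @classmethod
    def from_json(cls, path: str | Path, **kwargs) -> "CellLineageModel":
        """Build the model from a sites JSON file (see :mod:`sclineage.sites`)."""
        return cls(sites_from_json(path), **kwargs)

    @property
    def prepared(self) -> list[PreparedSite]:
        if self._prepared is None:
            self._prepared = [
                prepare_site(obs, max_coverage=self.max_coverage)
                for obs in self.sites
            ]
        return self._prepared

    def loglike(self, p_ado: float, p_ae: float) -> float:
        """Joint read log-likelihood at the given parameter values."""
        return data_log_likelihood(self.prepared, p_ado, p_ae, self.params)

    def estimate_parameters(self, config: MHConfig = MHConfig()) -> MHResult:
        """Metropolis-Hastings estimation of ``(p_ado, p_ae)`` from a site subset."""
        return mh_sample(self.prepared, config, self.params)

    def fit(
        self,
        n_boot: int = 0,
        seed: int = 0,
        jobs: int = 1,
        estimate: bool = False,
        mh_config: MHConfig | None = None,
        warn: bool = True,
    ) -> "CellLineageResults":
        """Compute distances, reconstruct the tree, optionally bootstrap.

        With ``estimate=True`` the dropout and amplification-error rates are
        first estimated by MCMC and used in place of the configured values.
        """
        params = self.params
        mh_result = None
        if estimate:
            mh_result = self.estimate_parameters(mh_config or MHConfig(seed=seed))
            params = ModelParameters(
                p_ado=mh_result.p_ado,
                p_ae=mh_result.p_ae,
                alpha=params.alpha,
                a=params.a,
                b=params.b,
            )
        prepared = self.prepared
        if jobs > 1:
            results = Parallel(n_jobs=jobs)(
                delayed(site_distance_matrix)(ps, params) for ps in prepared
            )
        else:
            results = [site_distance_matrix(ps, params) for ps in prepared]
        site_values = np.stack([r[0] for r in results])
        site_masks = np.stack([r[1] for r in results])
        distances = aggregate_distances(site_values, site_masks, self.labels, warn=warn)
        tree = reroot_at_bulk(neighbor_joining(distances.values, self.labels))
        boots: list[dendropy.Tree] = []
        supports = None
        if n_boot > 0:
            boots = bootstrap_trees(
                site_values, site_masks, self.labels, n_boot, seed
            )
            supports = tbe_supports(tree, boots)
        return CellLineageResults(
            model=self,
            params=params,
            distances=distances,
            tree=tree,
            bootstrap=boots,
            supports=supports,
            mh_result=mh_result,
        )


@dataclass
class CellLineageResults:
    """Fitted distances, tree and (optional) bootstrap supports."""

    model: CellLineageModel
    params: ModelParameters
    distances: DistanceMatrix
    tree: dendropy.Tree
    bootstrap: list[dendropy.Tree] = field(default_factory=list)
    supports: dict | None = None
    mh_result: MHResult | None = None

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def summary(self) -> str:
        """Human-readable account of the fit."""
        sites = self.model.sites
        kinds = {}
        for obs in sites:
            kinds[obs.kind] = kinds.get(obs.kind, 0) + 1
        off = ~np.eye(len(self.model.labels), dtype=bool)
        lines = [
            "Cell lineage reconstruction",
            "===========================",
            f"cells:               {self.model.n_cells} (+ bulk)",
            "sites:               "
            + ", ".join(f"{v} {k}" for k, v in sorted(kinds.items())),
            f"p_ado:               {self.params.p_ado:.4g}"
            + ("  (MCMC estimate)" if self.mh_result else ""),
            f"p_ae:                {self.params.p_ae:.4g}"
            + ("  (MCMC estimate)" if self.mh_result else ""),
            f"mean pair distance:  {self.distances.values[off].mean():.4f}",
        ]
        if self.bootstrap:
            vals = sorted(self.supports.values()) if self.supports else []
            lines.append(f"bootstrap trees:     {len(self.bootstrap)}")
            if vals:
                lines.append(
                    f"TBE supports:        min {vals[0]:.2f}, "
                    f"median {vals[len(vals) // 2]:.2f}, max {vals[-1]:.2f}"
                )
        lines.append("tree: " + self.newick())
        return "\n".join(lines)
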