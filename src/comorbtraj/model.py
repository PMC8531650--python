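"""Model/results objects tying the per-comorbidity GEE fits together.

`TrajectoryGEE` is built from a :class:`~comorbtraj.codes.PrevalencePanel`
(matched cases and controls with yearly presence indicators); ``fit()``
returns a :class:`TrajectoryGEEResults` carrying every comorbidity's
estimates, robust standard errors, Wald p-values and Benjamini-Hochberg
q-values, with ``summary()``, ``odds_ratios()`` and ``cluster()`` methods.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .codes import PrevalencePanel
from .gee import PARAM_NAMES, GeeFit, ModelSpec, fdr_adjust, fit_trajectory_gee, odds_ratio_table

logger = logging.getLogger(__name__)


class TrajectoryGEE:
    """Per-comorbidity logistic GEE trajectory model over a matched panel.

    Parameters
    ----------
    panel
        Matched prevalence panel (members x comorbidities x yearly intervals).
    spec
        Model configuration (time coding, centering, working correlation).
    fdr_family
        ``"separate"`` applies Benjamini-Hochberg within the centered-alpha
        p-values and within the gamma p-values as two families across
        comorbidities; ``"pooled"`` adjusts both together.
    """

    def __init__(
        self,
        panel: PrevalencePanel,
        spec: ModelSpec | None = None,
        fdr_family: str = "separate",
    ) -> None:
        if fdr_family not in ("separate", "pooled"):
            raise ValueError("fdr_family must be 'separate' or 'pooled'")
        self.panel = panel
        self.spec = spec or ModelSpec()
        self.fdr_family = fdr_family

    @classmethod
    def from_tables(
        cls,
        claims: pd.DataFrame,
        members: pd.DataFrame,
        code_map=None,
        threshold: float = 0.05,
        **kwargs,
    ) -> "TrajectoryGEE":
        """Build the model straight from claims and matched-member tables."""
        from .codes import build_yearly_panel, prevalence_filter

        panel = build_yearly_panel(claims, members, code_map)
        panel, _ = prevalence_filter(panel, threshold)
        return cls(panel, **kwargs)

    def fit(self, fallback: bool = True) -> "TrajectoryGEEResults":
        panel = self.panel
        is_case = panel.is_case
        fits: list[GeeFit] = []
        for ci, label in enumerate(panel.comorbidities):
            fit = fit_trajectory_gee(
                panel.indicators[:, ci, :], is_case, self.spec, label=label, fallback=fallback
            )
            if not fit.converged:
                logger.warning("comorbidity %s did not converge; excluded downstream", label)
            fits.append(fit)
        self._attach_qvalues(fits)
        return TrajectoryGEEResults(self, fits)

    def _attach_qvalues(self, fits: Sequence[GeeFit]) -> None:
        conv = [f for f in fits if f.converged]
        if not conv:
            return
        p_alpha = np.array([f.p_alpha_centered for f in conv])
        p_gamma = np.array([f.p_gamma for f in conv])
        if self.fdr_family == "separate":
            q_alpha = fdr_adjust(p_alpha)
            q_gamma = fdr_adjust(p_gamma)
        else:
            q = fdr_adjust(np.concatenate([p_alpha, p_gamma]))
            q_alpha, q_gamma = q[: len(conv)], q[len(conv):]
        for f, qa, qg in zip(conv, q_alpha, q_gamma):
            f.q_alpha_centered = float(qa)
            f.q_gamma = float(qg)


class TrajectoryGEEResults:
    """Fitted per-comorbidity trajectory models."""

    def __init__(self, model: TrajectoryGEE, fits: Sequence[GeeFit]) -> None:
        self.model = model
        self.fits = list(fits)

    @property
    def converged_fits(self) -> list[GeeFit]:
        return [f for f in self.fits if f.converged]

    def frame(self) -> pd.DataFrame:
        """One row per comorbidity: estimates, robust SEs, p, q, diagnostics."""
        rows = []
        for f in self.fits:
            se = f.se
            row = {"comorbidity": f.label}
            for i, name in enumerate(PARAM_NAMES):
                row[name] = f.params[i]
                row[f"se_{name}"] = se[i]
            row.update(
                p_alpha_centered=f.p_alpha_centered,
                p_gamma=f.p_gamma,
                q_alpha_centered=f.q_alpha_centered,
                q_gamma=f.q_gamma,
                converged=f.converged,
                correlation=f.correlation,
                t_bar=f.t_bar,
                n_members=f.n_members,
                n_obs=f.n_obs,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def odds_ratios(self) -> pd.DataFrame:
        return odds_ratio_table(self.converged_fits)

    def cluster(
        self,
        k: int = 5,
        standardize: bool = True,
        signed_logp: bool = True,
        prevalence: pd.DataFrame | None = None,
    ):
        """PCA + Ward clustering of the four model-derived metrics."""
        from .cluster import cluster_comorbidities

        return cluster_comorbidities(
            self.converged_fits, k=k, standardize=standardize,
            signed_logp=signed_logp,
        )

    def summary(self) -> str:
        """Readable per-comorbidity summary of effects and evidence."""
        frame = self.frame()
        n_conv = int(frame["converged"].sum())
        lines = [
            "Comorbidity trajectory GEE (logistic, sandwich covariance)",
            f"members: {self.model.panel.n_members}   intervals: {self.model.panel.n_intervals}"
            f"   comorbidities: {len(self.fits)} ({n_conv} converged)",
            f"working correlation requested: {self.model.spec.working_correlation}",
            "",
        ]
        cols = [
            "comorbidity", "alpha", "se_alpha", "q_alpha_centered",
            "gamma", "se_gamma", "q_gamma", "correlation",
        ]
        with pd.option_context("display.width", 120, "display.max_rows", 400):
            lines.append(frame[cols].round(4).to_string(index=False))
        return "\n".join(lines)
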