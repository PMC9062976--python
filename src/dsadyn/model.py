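"""End-to-end DSA dynamic-response model: data in, fitted grouping out.

`DsaResponseModel` bundles the four-stage pipeline — responder gating,
max-scaling, DTW mean-linkage clustering with gap-statistic k selection, and
nearest-mean classification of shorter series — behind a statsmodels-style
interface: build the model from the long-format MFI table (plus an optional
covariate/outcome table), call :meth:`fit`, and work with the returned
:class:`DsaResponseResults` (assignments, gap curve, summary tables,
outcome associations, Kaplan-Meier comparison).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc
from .cluster import ClusterModel, agglomerate, classify_short, label_archetypes
from .dtw import DEFAULT_PIPELINE_WINDOW, DtwConfig
from .gapstat import GapCurve, ReferenceConfig, gap_curve, select_k
from .preprocess import PreprocessConfig, preprocess_cohort
from .synth import ARCHETYPE_NAMES, archetype_skeletons

__all__ = ["DsaResponseModel", "DsaResponseResults"]

MODULATION_GROUPS = (1, 2)
SUSTAINED_GROUPS = (3, 4)


class DsaResponseModel:
    """Unsupervised grouping of early post-transplant tDSA trajectories.

    Parameters
    ----------
    mfi : DataFrame
        Long-format records ``case_id, specificity, day, mfi``.
    covariates : DataFrame, optional
        Per-case table with at least ``case_id``; outcome columns
        ``rejection_30d``, ``gf_5y``, ``followup_days`` unlock the
        association/survival methods of the results object.
    k : "auto" or int
        "auto" selects k by the gap statistic; an integer forces the cut.
    """

    def __init__(
        self,
        mfi: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        *,
        preprocess_config: PreprocessConfig | None = None,
        dtw_config: DtwConfig | None = None,
        reference_config: ReferenceConfig | None = None,
        k: int | str = "auto",
        k_max: int = 10,
    ) -> None:
        required = {"case_id", "specificity", "day", "mfi"}
        missing = required - set(mfi.columns)
        if missing:
            raise ValueError(f"mfi table missing columns {sorted(missing)}")
        self.mfi = mfi
        self.covariates = covariates
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.dtw_config = dtw_config or DtwConfig(window=DEFAULT_PIPELINE_WINDOW)
        self.reference_config = reference_config or ReferenceConfig()
        self.k = k
        self.k_max = k_max

    @classmethod
    def from_csv(cls, mfi_path, covariates_path=None, **kwargs) -> "DsaResponseModel":
        mfi = pd.read_csv(mfi_path, comment="#")
        cov = pd.read_csv(covariates_path, comment="#") if covariates_path else None
        return cls(mfi, cov, **kwargs)

    def fit(self, seed: int | None = None) -> "DsaResponseResults":
        """Run gating, clustering, k selection and short-series classification.

        ``seed`` overrides the reference-set RNG seed for the gap statistic.
        """
        stages = preprocess_cohort(self.mfi, self.preprocess_config)
        full, short, gated = stages["full_50"], stages["short_20_50"], stages["gated"]

        curve = None
        if len(full) >= 2:
            series = [tr.scaled for tr in full]
            if self.k == "auto":
                ref_cfg = self.reference_config
                if seed is not None:
                    ref_cfg = ReferenceConfig(
                        n_reference_sets=ref_cfg.n_reference_sets,
                        block_length=ref_cfg.block_length,
                        reference_size=ref_cfg.reference_size,
                        rng_seed=seed,
                    )
                k_cap = min(self.k_max, len(series) - 1)
                curve = gap_curve(series, k_cap, ref_cfg, self.dtw_config)
                k = select_k(curve)
            else:
                k = int(self.k)
            tree = agglomerate(series, self.dtw_config)
            labels_full = tree.cut(k)
            means = tree.cluster_means(k)
            labels_short = (
                classify_short(
                    [tr.scaled for tr in short],
                    means,
                    DtwConfig(window=self.dtw_config.window, normalize=True),
                )
                if short
                else np.array([], dtype=int)
            )
            archetype_map = label_archetypes(means, archetype_skeletons())
        else:  # degenerate cohort: everything gated, clustering skipped
            k, tree, means, archetype_map = 0, None, [], {}
            labels_full = np.array([], dtype=int)
            labels_short = np.array([], dtype=int)

        rows = []
        for tr in gated:
            rows.append((tr.case_id, 0, "no_response", "gated", tr.pre_treatment_tdsa))
        for tr, lab in zip(full, labels_full):
            rows.append(
                (
                    tr.case_id,
                    int(lab),
                    ARCHETYPE_NAMES.get(archetype_map.get(int(lab)), "unknown"),
                    "clustered",
                    tr.pre_treatment_tdsa,
                )
            )
        for tr, lab in zip(short, labels_short):
            rows.append(
                (
                    tr.case_id,
                    int(lab),
                    ARCHETYPE_NAMES.get(archetype_map.get(int(lab)), "unknown"),
                    "classified",
                    tr.pre_treatment_tdsa,
                )
            )
        assignments = pd.DataFrame(
            rows,
            columns=["case_id", "cluster", "archetype", "stage", "pre_treatment_tdsa"],
        ).sort_values("case_id", ignore_index=True)
        # semantic group id (0..4) from the archetype mapping
        name_to_group = {v: g for g, v in ARCHETYPE_NAMES.items()}
        assignments["group"] = assignments["archetype"].map(name_to_group).astype("Int64")

        return DsaResponseResults(
            model=self,
            assignments=assignments,
            selected_k=k,
            gap=curve,
            tree=tree,
            cluster_means=means,
            archetype_map=archetype_map,
            stages=stages,
        )


@dataclass
class DsaResponseResults:
    """Fitted grouping plus downstream association statistics."""

    model: DsaResponseModel
    assignments: pd.DataFrame
    selected_k: int
    gap: GapCurve | None
    tree: ClusterModel | None
    cluster_means: list[np.ndarray]
    archetype_map: dict[int, int]
    stages: dict = field(repr=False, default_factory=dict)

    @property
    def group_sizes(self) -> pd.Series:
        return self.assignments["group"].value_counts().sort_index()

    def _merged(self) -> pd.DataFrame:
        if self.model.covariates is None:
            raise ValueError("no covariate table was supplied to the model")
        return self.assignments.merge(self.model.covariates, on="case_id")

    def response_type(self) -> pd.Series:
        """modulation / sustained / no_response per case (indexed by case_id)."""
        def kind(g):
            if g in MODULATION_GROUPS:
                return "modulation"
            if g in SUSTAINED_GROUPS:
                return "sustained"
            return "no_response"

        return pd.Series(
            [kind(g) for g in self.assignments["group"]],
            index=self.assignments["case_id"],
            name="response_type",
        )

    def outcome_rates(self) -> pd.DataFrame:
        """Early-rejection and 5-year graft-failure rates per group."""
        df = self._merged()
        return df.groupby("group").agg(
            n=("case_id", "count"),
            rejection_rate=("rejection_30d", "mean"),
            gf_5y_rate=("gf_5y", "mean"),
        )

    def modulation_vs_sustained_table(self, column: str) -> assoc.ContingencyTable2x2:
        """2x2 table (rows modulation/sustained, cols outcome no/yes)."""
        df = self._merged()
        df["response_type"] = self.response_type().loc[df["case_id"]].to_numpy()
        df = df[df["response_type"].isin(["modulation", "sustained"])]
        mod = df[df["response_type"] == "modulation"][column]
        sus = df[df["response_type"] == "sustained"][column]
        return assoc.ContingencyTable2x2(
            a=int((mod == 0).sum()),
            b=int((mod == 1).sum()),
            c=int((sus == 0).sum()),
            d=int((sus == 1).sum()),
        )

    def km_modulation_vs_sustained(self) -> assoc.KaplanMeierResult:
        """5-year graft-survival comparison, modulation vs sustained."""
        df = self._merged()
        df["response_type"] = self.response_type().loc[df["case_id"]].to_numpy()
        df = df[df["response_type"].isin(["modulation", "sustained"])]
        return assoc.kaplan_meier(
            df["followup_days"], df["gf_5y"], df["response_type"]
        )

    def summary(self) -> str:
        lines = [
            "DSA dynamic-response model",
            "=" * 48,
            f"cases: {len(self.assignments)}   selected k: {self.selected_k}",
            "",
            "group  archetype           n",
        ]
        counts = self.assignments.groupby(["group", "archetype"]).size()
        for (g, name), n in counts.items():
            lines.append(f"{g!s:>5}  {name:<18} {n:>3}")
        if self.gap is not None:
            lines += ["", "k    gap      s_k      one-SE criterion"]
            crit = self.gap.ose_criterion_k
            for k, g, s, c in zip(
                self.gap.k_values, self.gap.gap_k, self.gap.s_k, crit
            ):
                mark = " <- selected" if k == self.selected_k else ""
                c_str = f"{c:+.4f}" if np.isfinite(c) else "   -  "
                lines.append(f"{k:<4} {g:+.4f}  {s:.4f}   {c_str}{mark}")
        try:
            rates = self.outcome_rates()
        except ValueError:
            rates = None
        if rates is not None:
            lines += ["", "group  n   rejection_30d  gf_5y"]
            for g, row in rates.iterrows():
                lines.append(
                    f"{g!s:>5} {int(row['n']):>3}   {row['rejection_rate']:>10.1%}  {row['gf_5y_rate']:>6.1%}"
                )
        return "\n".join(lines)
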