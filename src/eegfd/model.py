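"""Cohort-level model object tying the pipeline together.

:class:`HFDCohortModel` is constructed from a covariate table and a
per-channel HFD table (either measured from recordings with
:func:`eegfd.pipeline.run_subject` or simulated with
:func:`eegfd.simulate.make_cohort`); :meth:`HFDCohortModel.fit` runs the
whole statistical battery and returns a :class:`CohortResults` carrying
descriptives, the age fit, the correlation set, the ANOVA tables and the
interhemispheric-symmetry analyses, with a ``summary()`` report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as st
from .biochem import compute_ncc
from .regions import (
    HArSProfile,
    RegionMap,
    RegionalProfile,
    default_region_map,
    regional_hars,
    regional_means,
)

logger = logging.getLogger(__name__)

__all__ = ["HFDCohortModel", "CohortResults"]

GROUP_ORDER = ("YC", "EC", "AD")


class HFDCohortModel:
    """Regional EEG-complexity model of a three-group cohort.

    Parameters
    ----------
    covariates
        One row per subject (index = subject id) with columns ``group``
        (YC/EC/AD), ``age`` and optionally ``sex``, ``education_years``,
        ``mmse``, ``serum_copper_umol_l``, ``ceruloplasmin_mg_dl`` or a
        precomputed ``ncc_umol_l`` (which overrides the computation).
    channel_hfd
        Subjects x channels table of windowed HFD values.
    region_map
        Channel grouping; defaults to the study's literal map.
    """

    def __init__(
        self,
        covariates: pd.DataFrame,
        channel_hfd: pd.DataFrame,
        region_map: RegionMap | None = None,
        *,
        whole_brain_channels: str = "all",
    ) -> None:
        missing = channel_hfd.index.difference(covariates.index)
        if len(missing):
            raise ValueError(f"subjects without covariates: {list(missing)[:5]}")
        ids = [sid for sid in covariates.index if sid in channel_hfd.index]
        if not ids:
            raise ValueError("no subjects shared between tables")
        self.covariates = covariates.loc[ids].copy()
        if "group" not in self.covariates:
            raise ValueError("covariates need a 'group' column")
        self.channel_hfd = channel_hfd.loc[ids].astype(float)
        self.region_map = region_map or default_region_map()
        self.whole_brain_channels = whole_brain_channels
        self._attach_ncc()
        self.profiles: dict[str, RegionalProfile] = {}
        self.hars_profiles: dict[str, HArSProfile] = {}
        for sid in ids:
            per_channel = self.channel_hfd.loc[sid].dropna().to_dict()
            self.profiles[sid] = regional_means(
                per_channel, self.region_map,
                whole_brain_channels=whole_brain_channels, subject_id=sid,
            )
            self.hars_profiles[sid] = regional_hars(
                per_channel, self.region_map, subject_id=sid
            )

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        channel_columns: list[str] | None = None,
        **kwargs,
    ) -> "HFDCohortModel":
        """Build from one joined table (covariates + per-channel columns)."""
        from .preprocessing import MONTAGE_19, normalize_label

        if channel_columns is None:
            channel_columns = [
                c for c in table.columns if normalize_label(str(c)) in MONTAGE_19
            ]
        if not channel_columns:
            raise ValueError("no channel columns recognised")
        chan = table[channel_columns].copy()
        chan.columns = [normalize_label(str(c)) for c in channel_columns]
        cov = table.drop(columns=channel_columns)
        return cls(cov, chan, **kwargs)

    def _attach_ncc(self) -> None:
        cov = self.covariates
        if "ncc_umol_l" in cov.columns:
            return
        if {"serum_copper_umol_l", "ceruloplasmin_mg_dl"} <= set(cov.columns):
            ncc = []
            for _, row in cov.iterrows():
                cu, cp = row["serum_copper_umol_l"], row["ceruloplasmin_mg_dl"]
                if pd.notna(cu) and pd.notna(cp):
                    ncc.append(compute_ncc(float(cu), float(cp)).ncc)
                else:
                    ncc.append(np.nan)
            cov["ncc_umol_l"] = ncc
        else:
            cov["ncc_umol_l"] = np.nan

    # -- assembled views ----------------------------------------------------

    def frame(self) -> pd.DataFrame:
        """Covariates joined with whole-brain, regional and HArS values."""
        rows = {}
        for sid, prof in self.profiles.items():
            row = {"whole_brain_hfd": prof.whole_brain}
            for region, cells in prof.hfd.items():
                row[f"hfd_{region}_left"] = cells["left"]
                row[f"hfd_{region}_right"] = cells["right"]
                row[f"hfd_{region}"] = 0.5 * (cells["left"] + cells["right"])
            for region, v in self.hars_profiles[sid].hars.items():
                row[f"hars_{region}"] = v
            rows[sid] = row
        return self.covariates.join(pd.DataFrame.from_dict(rows, orient="index"))

    def fit(self, *, min_group_n: int = 2) -> "CohortResults":
        """Run the full statistical battery; skips with a log what the
        cohort cannot support (e.g. single-subject groups)."""
        frame = self.frame()
        groups = self.covariates["group"].to_dict()
        res = CohortResults(model=self, frame=frame)
        res.descriptives = self._descriptives(frame)
        sizes = frame["group"].value_counts()
        can_test = (sizes >= min_group_n).all() and len(sizes) >= 2 and len(frame) >= 5

        healthy = frame[frame["group"].isin(["YC", "EC"])]
        elderly = frame[frame["group"].isin(["EC", "AD"])]
        ad = frame[frame["group"] == "AD"]

        # age relationship in healthy subjects
        try:
            res.quadratic_age = st.fit_quadratic(
                healthy["age"], healthy["whole_brain_hfd"],
                name="whole-brain HFD ~ age (healthy, parabola)",
            )
        except ValueError as exc:
            logger.info("quadratic fit skipped: %s", exc)
        for label, sub in (("YC", frame[frame["group"] == "YC"]), ("EC", frame[frame["group"] == "EC"])):
            if len(sub) >= 4 and np.ptp(sub["whole_brain_hfd"]) > 0:
                res.correlations[f"age~HFD ({label})"] = st.correlate(
                    sub["age"], sub["whole_brain_hfd"], method="pearson",
                    name=f"age vs whole-brain HFD ({label})",
                )

        # cognition and copper
        def _corr(key, sub, xcol, ycol, method, name):
            data = sub[[xcol, ycol]].dropna()
            if len(data) >= 4 and np.ptp(data[xcol]) > 0 and np.ptp(data[ycol]) > 0:
                res.correlations[key] = st.correlate(
                    data[xcol], data[ycol], method=method, name=name
                )

        _corr("mmse~HFD (elderly)", elderly, "mmse", "whole_brain_hfd",
              "spearman", "MMSE vs whole-brain HFD (EC+AD)")
        _corr("mmse~HFD (AD)", ad, "mmse", "whole_brain_hfd",
              "spearman", "MMSE vs whole-brain HFD (AD)")
        _corr("ncc~HFD (elderly)", elderly, "ncc_umol_l", "whole_brain_hfd",
              "pearson", "NCC vs whole-brain HFD (EC+AD)")
        _corr("ncc~HFD (AD)", ad, "ncc_umol_l", "whole_brain_hfd",
              "pearson", "NCC vs whole-brain HFD (AD)")
        _corr("ncc~parietal HFD (AD)", ad.assign(
            parietal=ad["hfd_parietal"]), "ncc_umol_l", "parietal",
              "pearson", "NCC vs parietal HFD (AD)")
        trip = elderly[["ncc_umol_l", "whole_brain_hfd", "mmse"]].dropna()
        if len(trip) >= 5:
            res.correlations["ncc~HFD | mmse (elderly)"] = st.partial_correlation(
                trip["ncc_umol_l"], trip["whole_brain_hfd"], trip["mmse"],
                name="NCC vs whole-brain HFD controlling MMSE (EC+AD)",
            )

        res.matching = st.matching_tests(frame)

        if can_test:
            profs = {sid: p.hfd for sid, p in self.profiles.items()}
            regions = list(self.region_map.regions())
            res.full_anova = st.full_anova(profs, groups, regions)
            res.reduced = st.reduced_anovas(profs, groups, regions)
            hars_maps = {sid: p.hars for sid, p in self.hars_profiles.items()}
            res.hars = st.hars_anova(hars_maps, groups, covariates=frame, regions=regions)
        else:
            logger.info(
                "ANOVA battery skipped: group sizes %s insufficient", sizes.to_dict()
            )
        return res

    def _descriptives(self, frame: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for group in [g for g in GROUP_ORDER if g in set(frame["group"])]:
            sub = frame[frame["group"] == group]
            sexes = sub["sex"].value_counts() if "sex" in sub else {}
            row = {
                "group": group,
                "n": len(sub),
                "m_f": f"{sexes.get('M', 0)}/{sexes.get('F', 0)}" if len(sexes) else "",
            }
            for col, label in (
                ("age", "age"),
                ("education_years", "education"),
                ("mmse", "mmse"),
                ("whole_brain_hfd", "hfd"),
                ("ncc_umol_l", "ncc"),
            ):
                if col in sub:
                    vals = pd.to_numeric(sub[col], errors="coerce").dropna()
                    row[f"{label}_mean"] = float(vals.mean()) if len(vals) else np.nan
                    row[f"{label}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            rows.append(row)
        return pd.DataFrame(rows).set_index("group")


@dataclass
class CohortResults:
    """Everything :meth:`HFDCohortModel.fit` computed."""

    model: HFDCohortModel
    frame: pd.DataFrame
    descriptives: pd.DataFrame | None = None
    quadratic_age: st.StatResult | None = None
    correlations: dict[str, st.StatResult] = field(default_factory=dict)
    matching: list[st.StatResult] = field(default_factory=list)
    full_anova: pd.DataFrame | None = None
    reduced: dict[str, dict] | None = None
    hars: dict[str, dict] | None = None

    def group_mean_hfd(self) -> pd.Series:
        return self.frame.groupby("group")["whole_brain_hfd"].mean()

    def summary(self) -> str:
        """Plain-text report of descriptives and every test."""
        lines: list[str] = []
        add = lines.append
        add("Cohort HFD analysis")
        add("=" * 60)
        if self.descriptives is not None:
            add("Descriptives (mean +/- SD):")
            for g, row in self.descriptives.iterrows():
                bits = [f"{g}: n={int(row['n'])}"]
                if row.get("m_f"):
                    bits.append(f"M/F={row['m_f']}")
                for label in ("age", "education", "mmse", "hfd", "ncc"):
                    m = row.get(f"{label}_mean")
                    s = row.get(f"{label}_sd")
                    if m is not None and np.isfinite(m):
                        prec = 3 if label == "hfd" else 1
                        bits.append(f"{label}={m:.{prec}f}+/-{s:.{prec}f}"
                                    if s is not None and np.isfinite(s)
                                    else f"{label}={m:.{prec}f}")
                add("  " + ", ".join(bits))
        if self.quadratic_age is not None:
            e = self.quadratic_age.effect
            add("")
            add(f"Age fit (healthy, parabola): hfd = {e['a']:.3g}*age^2 + {e['b']:.3g}*age "
                f"+ {e['c']:.3g}; R2={e['r2']:.3f}, vertex={e['vertex_age']:.1f} y, "
                f"p={self.quadratic_age.p:.4g}")
        if self.correlations:
            add("")
            add("Correlations:")
            for r in self.correlations.values():
                add(f"  {r}")
        if self.matching:
            add("")
            add("Group matching:")
            for r in self.matching:
                add(f"  {r}")
        if self.full_anova is not None:
            add("")
            add("Full mixed ANOVA (region x hemisphere x group):")
            tbl = self.full_anova[["F", "df1_corr", "df2_corr", "p_corr", "eps_gg"]]
            add(tbl.to_string(float_format=lambda v: f"{v:.4g}"))
        if self.reduced:
            add("")
            add("Reduced models per region (hemisphere x group) + post-hocs:")
            for region, entry in self.reduced.items():
                grp = entry["anova"].loc["group"]
                add(f"  {region}: group F({grp['df1']:.0f},{grp['df2']:.0f})="
                    f"{grp['F']:.2f}, p={grp['p']:.4g}")
                for r in entry["posthoc"]:
                    add(f"    {r}")
        if self.hars:
            add("")
            add("HArS one-way ANOVAs:")
            for region, entry in self.hars.items():
                add(f"  {entry['omnibus']}")
                for key in ("corr_age", "corr_mmse"):
                    if key in entry:
                        add(f"    {entry[key]}")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_age_curve(self, ax=None):
        """Whole-brain HFD vs age with the fitted parabola (healthy)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.frame[self.frame["group"].isin(["YC", "EC"])]
        ax.scatter(sub["age"], sub["whole_brain_hfd"], s=18, label="healthy")
        if self.quadratic_age is not None:
            e = self.quadratic_age.effect
            xs = np.linspace(sub["age"].min(), sub["age"].max(), 200)
            ax.plot(xs, e["a"] * xs**2 + e["b"] * xs + e["c"], "r-",
                    label=f"parabola (R2={e['r2']:.2f})")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("whole-brain HFD")
        ax.legend()
        return ax

    def plot_hars(self, ax=None):
        """Mean regional HArS per group with SEM bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        regions = list(self.model.region_map.regions())
        x = np.arange(len(regions))
        width = 0.8 / max(1, self.frame["group"].nunique())
        for i, g in enumerate([g for g in GROUP_ORDER if g in set(self.frame["group"])]):
            sub = self.frame[self.frame["group"] == g]
            means = [sub[f"hars_{r}"].mean() for r in regions]
            sems = [sub[f"hars_{r}"].sem() for r in regions]
            ax.bar(x + i * width, means, width, yerr=sems, label=g)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xticks(x + width)
        ax.set_xticklabels(regions)
        ax.set_ylabel("HFD HArS")
        ax.legend()
        return ax
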