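"""Pipeline orchestration: recordings -> per-channel HFD -> cohort model.

``run_subject`` composes the signal stages in order (preprocess, windowed
Higuchi estimation per channel, regional aggregation, symmetry index);
``run_cohort`` applies them over a manifest — or starts from a
precomputed per-channel HFD table — and fits :class:`HFDCohortModel`.
``ingest_s1`` adapts a deposited per-subject spreadsheet (age, per-channel
HFD, MMSE, NCC) to the pipeline's native tables, inferring group
membership from an explicit column when present and otherwise from MMSE
availability (no MMSE -> young control; MMSE <= 24 -> AD; else elderly
control), with the applied rule logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .higuchi import (
    DEFAULT_K_MAX,
    DEFAULT_WINDOW_SECONDS,
    kmax_sweep,
    windowed_hfd,
)
from .model import CohortResults, HFDCohortModel
from .preprocessing import (
    EEGRecording,
    PreprocessConfig,
    load_recording,
    preprocess,
    reject_windows,
)
from .regions import (
    RegionMap,
    default_region_map,
    regional_hars,
    regional_means,
    strict_disjoint_region_map,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectResult", "run_subject", "run_cohort", "ingest_s1"]


@dataclass
class PipelineConfig:
    """End-to-end configuration; defaults are the study's choices
    (k_max = 65, 2 s windows, grid 2..128, alpha .05, trend band .10)."""

    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    k_max: int = DEFAULT_K_MAX
    window_seconds: float = DEFAULT_WINDOW_SECONDS
    fit_k_min: int = 1
    k_max_grid: tuple[int, int] = (2, 128)
    region_map: str = "literal"  # or "strict-disjoint" or a file path
    whole_brain_channels: str = "all"
    alpha: float = 0.05
    trend_alpha: float = 0.10
    seed: int = 0

    def resolve_region_map(self) -> RegionMap:
        if self.region_map == "literal":
            return default_region_map()
        if self.region_map == "strict-disjoint":
            return strict_disjoint_region_map()
        return RegionMap.from_file(self.region_map)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SubjectResult:
    subject_id: str
    channel_hfd: pd.Series  # per-channel windowed HFD
    regional: "pd.DataFrame"
    hars: "pd.Series"
    whole_brain: float
    n_windows: int
    n_rejected: int


def run_subject(
    recording: EEGRecording | str | Path, cfg: PipelineConfig | None = None
) -> SubjectResult:
    """Preprocess one recording and estimate its HFD profile."""
    cfg = cfg or PipelineConfig()
    if not isinstance(recording, EEGRecording):
        recording = load_recording(recording)
    try:
        rec = preprocess(recording, cfg.preprocessing)
        window_samples = int(round(rec.fs * cfg.window_seconds))
        keep = reject_windows(
            rec, window_samples, cfg.preprocessing.artifact_abs_threshold_uv
        )
        values = {}
        n_windows = 0
        for ch, series in zip(rec.channel_labels, rec.data):
            wh = windowed_hfd(
                series, rec.fs, cfg.window_seconds, cfg.k_max,
                fit_k_min=cfg.fit_k_min, keep_mask=keep,
            )
            values[ch] = wh.fd
            n_windows = wh.n_windows
    except Exception as exc:
        raise RuntimeError(f"subject {recording.subject_id!r}: {exc}") from exc
    rmap = cfg.resolve_region_map()
    prof = regional_means(
        values, rmap, whole_brain_channels=cfg.whole_brain_channels,
        subject_id=recording.subject_id,
    )
    hars_prof = regional_hars(values, rmap, subject_id=recording.subject_id)
    n_rej = int((~keep).sum())
    logger.info(
        "subject %s: %d channels, %d windows used, %d rejected",
        recording.subject_id, len(values), n_windows, n_rej,
    )
    regional = pd.DataFrame(
        [
            {"region": r, "hemisphere": h, "hfd": prof.hfd[r][h]}
            for r in prof.hfd
            for h in ("left", "right")
        ]
    )
    return SubjectResult(
        subject_id=recording.subject_id,
        channel_hfd=pd.Series(values, name=recording.subject_id),
        regional=regional,
        hars=pd.Series(hars_prof.hars, name=recording.subject_id),
        whole_brain=prof.whole_brain,
        n_windows=n_windows,
        n_rejected=n_rej,
    )


def run_cohort(
    covariates: pd.DataFrame,
    recordings: dict[str, EEGRecording | str | Path] | None = None,
    channel_hfd: pd.DataFrame | None = None,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> CohortResults:
    """Fit the cohort model from recordings or a precomputed HFD table.

    Exactly one of ``recordings`` / ``channel_hfd`` must be supplied.
    With ``out_dir`` the tidy tables and the text report are written,
    each stamped with the package version and config hash.
    """
    cfg = cfg or PipelineConfig()
    if (recordings is None) == (channel_hfd is None):
        raise ValueError("supply exactly one of recordings / channel_hfd")
    if recordings is not None:
        unmatched = [sid for sid in recordings if sid not in covariates.index]
        if unmatched:
            raise ValueError(f"recordings without covariates: {unmatched[:5]}")
        rows = {}
        for sid, rec in recordings.items():
            res = run_subject(rec, cfg)
            rows[sid] = res.channel_hfd
        channel_hfd = pd.DataFrame.from_dict(rows, orient="index")
    model = HFDCohortModel(
        covariates, channel_hfd, cfg.resolve_region_map(),
        whole_brain_channels=cfg.whole_brain_channels,
    )
    results = model.fit()
    if out_dir is not None:
        _write_bundle(results, cfg, Path(out_dir))
    return results


def _write_bundle(results: CohortResults, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = f"# eegfd {__version__} config={cfg.config_hash()}\n"
    frame_path = out_dir / "cohort_frame.tsv"
    with open(frame_path, "w") as fh:
        fh.write(stamp)
        results.frame.to_csv(fh, sep="\t")
    if results.full_anova is not None:
        with open(out_dir / "full_anova.tsv", "w") as fh:
            fh.write(stamp)
            results.full_anova.to_csv(fh, sep="\t")
    (out_dir / "report.txt").write_text(stamp + results.summary() + "\n")
    logger.info("results bundle written to %s", out_dir)


# --- deposited-dataset ingestion -------------------------------------------

_COLUMN_SYNONYMS = {
    "subject_id": {"subject", "subject_id", "id", "subj", "code", "participant"},
    "group": {"group", "grp", "diagnosis", "dx"},
    "age": {"age", "age_years", "age (years)"},
    "sex": {"sex", "gender"},
    "mmse": {"mmse", "mmse_score", "mmse score"},
    "ncc_umol_l": {"ncc", "free_copper", "free copper", "ncc_umol_l", "non-cp copper"},
    "education_years": {"education", "education_years", "years of education"},
    "serum_copper_umol_l": {"serum_copper", "copper", "serum copper"},
    "ceruloplasmin_mg_dl": {"ceruloplasmin", "cp"},
}


def _infer_group(row: pd.Series) -> str:
    if pd.isna(row.get("mmse", np.nan)):
        return "YC"
    if float(row["mmse"]) <= 24:
        if float(row["mmse"]) == 24:
            logger.warning(
                "subject %s: MMSE exactly 24, classified AD by the <=24 rule",
                row.name,
            )
        return "AD"
    return "EC"


def ingest_s1(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a deposited per-subject spreadsheet into pipeline tables.

    Returns ``(covariates, channel_hfd)`` indexed by subject id.  Column
    headers are matched case-insensitively against common synonyms and the
    19-channel montage (old or new nomenclature).  Without an explicit
    group column, groups are inferred from MMSE: absent -> YC,
    <= 24 -> AD, otherwise EC (the applied rule is logged).
    """
    from .preprocessing import MONTAGE_19, normalize_label

    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path, sep=None, engine="python")
    rename: dict[str, str] = {}
    channel_cols: dict[str, str] = {}
    for col in table.columns:
        key = str(col).strip().lower()
        norm = normalize_label(str(col).strip())
        if norm in MONTAGE_19:
            channel_cols[col] = norm
            continue
        for target, names in _COLUMN_SYNONYMS.items():
            if key in names:
                rename[col] = target
                break
    if not channel_cols:
        raise ValueError(
            f"{path}: no channel columns recognised in header {list(table.columns)}"
        )
    table = table.rename(columns=rename)
    if "subject_id" not in table.columns:
        table["subject_id"] = [f"S{i + 1:03d}" for i in range(len(table))]
    if "age" not in table.columns:
        raise ValueError(f"{path}: no age column in header {list(table.columns)}")
    table = table.set_index(table["subject_id"].astype(str)).drop(columns="subject_id")
    channel_hfd = table[list(channel_cols)].astype(float)
    channel_hfd.columns = [channel_cols[c] for c in channel_cols]
    cov = table.drop(columns=list(channel_cols))
    if "group" not in cov.columns:
        logger.info("no group column: inferring groups from MMSE (<=24 -> AD)")
        cov["group"] = cov.apply(_infer_group, axis=1)
    if "ncc_umol_l" in cov.columns:
        n_miss = int(cov["ncc_umol_l"].isna().sum())
        if n_miss:
            logger.info("NCC missing for %d subjects; NCC stats use complete cases", n_miss)
    return cov, channel_hfd


def sweep_cohort(
    recordings: dict[str, EEGRecording],
    cfg: PipelineConfig | None = None,
    groups: dict[str, str] | None = None,
):
    """k_max sweep over preprocessed whole-brain data of several subjects."""
    cfg = cfg or PipelineConfig()
    mats, ids, glab = [], [], []
    for sid, rec in recordings.items():
        pre = preprocess(rec, cfg.preprocessing)
        mats.append(pre.data)
        ids.append(sid)
        glab.append(groups.get(sid) if groups else None)
    lo, hi = cfg.k_max_grid
    return kmax_sweep(
        dict(zip(ids, mats)),
        fs=cfg.preprocessing.target_fs,
        k_max_grid=range(lo, hi + 1),
        window_seconds=cfg.window_seconds,
        fit_k_min=cfg.fit_k_min,
        groups=glab if groups else None,
    )
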