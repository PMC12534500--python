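"""End-to-end study orchestration.

``simulate_study`` materializes a synthetic crossover study on disk
(recordings, hypnograms, ground truth, manifest, config);
``run_pipeline`` consumes a :class:`StudyManifest` and produces every
analysis table: band power, ΔPSD z-scores, PLV edge lists, network
metrics, the paired-contrast families with FDR, the intervention ×
timepoint rm-ANOVA, sleep architecture/cycles, first-cycle NREM
spectra, and the wake→sleep correlation, plus a JSON summary. Reruns
on the same manifest are bit-identical: every stage is deterministic
given the input files.

The reporting stage only collates stats-module outputs; it recomputes
nothing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, network, preprocess, sleep, spectral, stats
from .bands import BANDS
from .errors import NoAnalyzableDataError, ValidationError
from .io import (read_hypnogram, read_recording, save_json, save_yaml,
                 write_delimited, write_edf, write_hypnogram)
from .simulate import (ARMS, TIMEPOINTS, SimConfig, simulate_sleep_night,
                       simulate_wake_recording)

logger = logging.getLogger(__name__)

PSD_COMPARISONS = (("T1", "T2"), ("T1", "T4"), ("T1", "T6"))


@dataclass
class StudyManifest:
    """Design table of the study: one row per recording file."""

    rows: pd.DataFrame        # kind, subject, arm, timepoint, path, hypnogram
    outdir: Path
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        required = {"kind", "subject", "arm", "path"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        wake = self.rows[self.rows["kind"] == "wake"]
        dup = wake.duplicated(subset=["subject", "arm", "timepoint"])
        if dup.any():
            raise ValidationError(
                f"duplicate (subject, arm, timepoint) rows:\n{wake[dup]}")
        for p in self.rows["path"]:
            if not Path(p).exists():
                raise ValidationError(f"manifest references missing file: {p}")

    @classmethod
    def from_csv(cls, path, outdir) -> "StudyManifest":
        return cls(pd.read_csv(path, dtype={"timepoint": str}), Path(outdir))


def simulate_study(cfg: SimConfig, outdir, file_format: str = "delimited",
                   timepoints=TIMEPOINTS, with_sleep: bool = True,
                   ) -> StudyManifest:
    """Generate and write the whole synthetic study; returns its manifest."""
    outdir = Path(outdir)
    data_dir = outdir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    writer = write_edf if file_format == "edf" else write_delimited
    ext = "edf" if file_format == "edf" else "tsv"
    rows = []
    truth: dict = {}
    for subject in range(cfg.n_subjects):
        for arm in ARMS:
            for tp in timepoints:
                rec, gt = simulate_wake_recording(cfg, subject, arm, tp)
                path = data_dir / f"sub{subject:02d}_{arm}_{tp}.{ext}"
                writer(rec, path)
                rows.append({"kind": "wake", "subject": subject, "arm": arm,
                             "timepoint": tp, "path": str(path),
                             "hypnogram": ""})
                truth[f"wake/{subject}/{arm}/{tp}"] = {
                    "band_power": gt.band_power,
                    "coupled_pairs": gt.coupled_pairs,
                    "artifact_epochs": gt.artifact_epochs,
                    "subject_effect": gt.subject_effect,
                }
            if with_sleep:
                rec, hyp, gt = simulate_sleep_night(cfg, subject, arm)
                path = data_dir / f"sub{subject:02d}_{arm}_sleep.{ext}"
                hpath = data_dir / f"sub{subject:02d}_{arm}_hypnogram.tsv"
                writer(rec, path)
                write_hypnogram(hyp, hpath)
                rows.append({"kind": "sleep", "subject": subject, "arm": arm,
                             "timepoint": "", "path": str(path),
                             "hypnogram": str(hpath)})
                truth[f"sleep/{subject}/{arm}"] = {
                    "stage_band_power": gt.stage_band_power,
                    "artifact_epochs": gt.artifact_epochs,
                    "subject_effect": gt.subject_effect,
                }
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    save_json(truth, outdir / "ground_truth.json")
    save_yaml(cfg.to_dict(), outdir / "config.yaml")
    return StudyManifest(manifest, outdir, cfg)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _wake_epochs(path) -> preprocess.EpochSet:
    rec = read_recording(path)
    rec = preprocess.preprocess_wake(rec)
    return preprocess.segment_and_reject(rec, preprocess.WAKE_EPOCH_S)


def wake_tables(manifest: StudyManifest, bands=BANDS):
    """Band power, PLV edges and network metrics for every wake row."""
    bp_rows, edge_rows, metric_rows = [], [], []
    tables: dict = {}
    plvs: dict = {}
    wake = manifest.rows[manifest.rows["kind"] == "wake"]
    for _, row in wake.iterrows():
        key = (row["subject"], row["arm"], row["timepoint"])
        try:
            es = _wake_epochs(row["path"])
        except NoAnalyzableDataError as exc:
            raise NoAnalyzableDataError(
                f"subject {row['subject']} {row['arm']} {row['timepoint']}: {exc}"
            ) from exc
        bp = spectral.band_power_from_epochs(es, bands=bands)
        tables[key] = bp
        tidy = bp.to_tidy()
        tidy["subject"], tidy["arm"], tidy["timepoint"] = key
        bp_rows.append(tidy[["subject", "arm", "timepoint",
                             "channel", "band", "power"]])
        for b in bands:
            mat = connectivity.plv_matrix(es, b)
            plvs[key + (b.name,)] = mat
            et = mat.to_edge_table()[["chan_a", "chan_b", "band", "plv"]]
            et["subject"], et["arm"], et["timepoint"] = key
            edge_rows.append(et)
            nm = network.network_metrics(mat).to_tidy()[["metric", "value"]]
            nm["subject"], nm["arm"], nm["timepoint"], nm["band"] = key + (b.name,)
            metric_rows.append(nm)
    return (pd.concat(bp_rows, ignore_index=True),
            pd.concat(edge_rows, ignore_index=True),
            pd.concat(metric_rows, ignore_index=True),
            tables, plvs)


def psd_contrast_families(bp: pd.DataFrame, alpha: float = 0.05,
                          comparisons=PSD_COMPARISONS) -> pd.DataFrame:
    """Paired t + FDR per (arm, band, comparison) family across electrodes."""
    out = []
    for (arm, band), grp in bp.groupby(["arm", "band"]):
        wide = grp.pivot_table(index="subject", columns=["timepoint", "channel"],
                               values="power")
        for ta, tb in comparisons:
            if ta not in wide.columns.levels[0] or tb not in wide.columns.levels[0]:
                continue
            res = stats.paired_t_fdr(wide[ta], wide[tb], alpha=alpha,
                                     band=band, comparison=(ta, tb))
            df = stats.results_to_frame(res)
            df["arm"] = arm
            out.append(df)
    return pd.concat(out, ignore_index=True)


def plv_contrast_families(edges: pd.DataFrame, alpha: float = 0.05,
                          comparisons=PSD_COMPARISONS) -> pd.DataFrame:
    """Paired t + FDR per (arm, band, comparison) family across edges."""
    edges = edges.assign(edge=edges["chan_a"] + "-" + edges["chan_b"])
    out = []
    for (arm, band), grp in edges.groupby(["arm", "band"]):
        wide = grp.pivot_table(index="subject", columns=["timepoint", "edge"],
                               values="plv")
        for ta, tb in comparisons:
            if ta not in wide.columns.levels[0] or tb not in wide.columns.levels[0]:
                continue
            res = stats.paired_t_fdr(wide[ta], wide[tb], alpha=alpha,
                                     band=band, comparison=(ta, tb))
            df = stats.results_to_frame(res)
            df["arm"] = arm
            out.append(df)
    return pd.concat(out, ignore_index=True)


def network_anova(metrics: pd.DataFrame) -> pd.DataFrame:
    """Intervention × timepoint rm-ANOVA per (band, metric)."""
    out = []
    for (band, metric), grp in metrics.groupby(["band", "metric"]):
        res = stats.rm_anova_2x6(grp.rename(columns={"value": "value"}),
                                 dv="value")
        for r in res:
            out.append({"band": band, "metric": metric, "effect": r.effect,
                        "F": r.F, "df_num": r.df_num, "df_den": r.df_den,
                        "p": r.p})
    return pd.DataFrame(out)


def sleep_stage_tables(manifest: StudyManifest, bands=BANDS):
    """Architecture, cycles, and first-cycle NREM band power per night."""
    arch_rows, cycle_rows, fc_rows = [], [], []
    nights = manifest.rows[manifest.rows["kind"] == "sleep"]
    for _, row in nights.iterrows():
        stages = read_hypnogram(row["hypnogram"])
        h = sleep.Hypnogram(stages)
        arch = sleep.score_architecture(h)
        arch_rows.append({"subject": row["subject"], "arm": row["arm"],
                          **vars(arch)})
        cycles = sleep.detect_cycles(h)
        for k, c in enumerate(cycles.cycles):
            cycle_rows.append({"subject": row["subject"], "arm": row["arm"],
                               "cycle": k + 1, **vars(c)})
        rec = read_recording(row["path"])
        try:
            bp, _plv = sleep.first_cycle_nrem_spectra(rec, h, cycles,
                                                      bands=bands)
        except NoAnalyzableDataError as exc:
            logger.warning("subject %s %s: %s", row["subject"], row["arm"], exc)
            continue
        tidy = bp.to_tidy()[["channel", "band", "power"]]
        tidy["subject"], tidy["arm"] = row["subject"], row["arm"]
        fc_rows.append(tidy)
    return (pd.DataFrame(arch_rows), pd.DataFrame(cycle_rows),
            pd.concat(fc_rows, ignore_index=True) if fc_rows else pd.DataFrame())


def wake_sleep_table(tables: dict, first_cycle_bp: pd.DataFrame,
                     channel: str = "F4", bands=("delta", "theta"),
                     ) -> pd.DataFrame:
    """Correlation of ΔPSD z-scores (T6−T1 at one electrode) with
    first-cycle NREM band power, per arm and band."""
    out = []
    for arm in ARMS:
        arm_tables = {}
        for (subject, a, tp), bp in tables.items():
            if a == arm:
                arm_tables.setdefault(subject, {})[tp] = bp
        if not arm_tables:
            continue
        # raises with the offending subjects listed if any lacks T1 or T6
        dz = spectral.delta_psd_zscores(arm_tables, channel=channel, arm=arm)
        for band in bands:
            zs = dz.table[dz.table["band"] == band].set_index("subject")["zscore"]
            sl = first_cycle_bp[(first_cycle_bp["arm"] == arm)
                                & (first_cycle_bp["band"] == band)
                                & (first_cycle_bp["channel"] == channel)]
            sl = sl.set_index("subject")["power"]
            common = zs.index.intersection(sl.index)
            if len(common) < 3:
                continue
            r, p, n = stats.wake_sleep_correlation(zs.loc[common], sl.loc[common])
            out.append({"arm": arm, "band": band, "channel": channel,
                        "r": r, "p": p, "n": n})
    return pd.DataFrame(out)


def run_pipeline(manifest: StudyManifest, alpha: float = 0.05,
                 display_alpha: float = 0.005, bands=BANDS) -> dict:
    """Run every analysis stage; write tables under ``manifest.outdir`` and
    return the table dict. ``display_alpha`` is the stricter threshold used
    only to flag network-figure edges in the summary."""
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wake = manifest.rows[manifest.rows["kind"] == "wake"]
    all_tps = set(wake["timepoint"])
    incomplete = sorted(
        f"subject {s} {a}: missing {sorted(all_tps - set(grp['timepoint']))}"
        for (s, a), grp in wake.groupby(["subject", "arm"])
        if set(grp["timepoint"]) != all_tps)
    if incomplete:
        raise ValidationError(
            "incomplete wake design (ΔPSD and the crossover contrasts need "
            "every timepoint per subject/arm): " + "; ".join(incomplete))
    bp, edges, metrics, tables, _plvs = wake_tables(manifest, bands=bands)
    out: dict = {"band_power": bp, "plv_edges": edges,
                 "network_metrics": metrics}
    out["psd_contrasts"] = psd_contrast_families(bp, alpha=alpha)
    out["plv_contrasts"] = plv_contrast_families(edges, alpha=alpha)
    n_tp = bp["timepoint"].nunique()
    if n_tp >= 2 and bp["arm"].nunique() == 2:
        out["network_anova"] = network_anova(metrics)
    have_sleep = (manifest.rows["kind"] == "sleep").any()
    if have_sleep:
        arch, cyc, fc = sleep_stage_tables(manifest, bands=bands)
        out["sleep_architecture"], out["sleep_cycles"] = arch, cyc
        out["first_cycle_band_power"] = fc
        if len(fc) and {"T1", "T6"} <= set(bp["timepoint"].unique()):
            out["wake_sleep_correlation"] = wake_sleep_table(tables, fc)
    for name, df in out.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    summary = {
        "alpha": alpha,
        "display_alpha": display_alpha,
        "n_wake_recordings": int((manifest.rows["kind"] == "wake").sum()),
        "n_sleep_nights": int((manifest.rows["kind"] == "sleep").sum()),
        "significant_psd_units": _sig_units(out["psd_contrasts"]),
        "significant_plv_edges": _sig_units(out["plv_contrasts"]),
        "display_threshold_plv_edges": _sig_units(
            out["plv_contrasts"], col="q", level=display_alpha),
    }
    save_json(summary, outdir / "summary.json")
    out["summary"] = summary
    return out


def crossover_recovery(cfg: SimConfig | None = None,
                       contrast_band: str = "theta",
                       pair: tuple = ("F4", "O1"),
                       baseline: str = "T1", post: str = "T6",
                       alpha: float = 0.05,
                       null_sims: int = 100,
                       null_seed: int = 12345) -> dict:
    """Parameter-recovery study: simulate the crossover in memory and
    measure how well the injected effects are recovered.

    For every subject × arm at the baseline and post timepoints the wake
    recording is generated, preprocessed, screened, and reduced to band
    power (all electrodes) and the PLV of the configured coupled pair.
    Returns per-arm counts of FDR-significant electrodes in the
    ``contrast_band`` baseline-vs-post contrast, the coupled pair's PLV
    distribution at the active post timepoint, and the matched-simulation
    null quantile for coupling detection.
    """
    cfg = cfg or SimConfig()
    bp_rows = []
    pair_plv: dict = {"active": [], "sham": []}
    for subject in range(cfg.n_subjects):
        for arm in ARMS:
            for tp in (baseline, post):
                rec, _gt = simulate_wake_recording(cfg, subject, arm, tp)
                rec = preprocess.preprocess_wake(rec)
                es = preprocess.segment_and_reject(rec)
                bp = spectral.band_power_from_epochs(es)
                tidy = bp.to_tidy()[["channel", "band", "power"]]
                tidy["subject"], tidy["arm"], tidy["timepoint"] = subject, arm, tp
                bp_rows.append(tidy)
                if tp == post:
                    mat = connectivity.plv_matrix(es, contrast_band)
                    pair_plv[arm].append(mat.value(*pair))
    bp = pd.concat(bp_rows, ignore_index=True)
    contrasts = psd_contrast_families(
        bp, alpha=alpha, comparisons=((baseline, post),))
    sub = contrasts[contrasts["band"] == contrast_band]
    sig = {arm: int(sub[(sub["arm"] == arm)]["significant"].sum())
           for arm in ARMS}
    n_units = int(sub[sub["arm"] == "active"]["unit"].nunique())
    n_epochs = int(cfg.wake_duration // preprocess.WAKE_EPOCH_S)
    null = connectivity.simulate_null_plv(
        contrast_band, cfg.sfreq_wake, preprocess.WAKE_EPOCH_S,
        n_epochs, n_sims=null_sims, seed=null_seed)
    return {
        "band_power": bp,
        "contrasts": contrasts,
        "n_units": n_units,
        "significant_electrodes": sig,
        "pair_plv": {k: np.asarray(v) for k, v in pair_plv.items()},
        "null_plv": null,
        "null_q95": float(np.quantile(null, 0.95)),
    }


def _sig_units(df: pd.DataFrame, col: str = "q", level: float | None = None):
    res = {}
    for (arm, band, comp), grp in df.groupby(["arm", "band", "comparison"]):
        if level is None:
            hits = grp[grp["significant"]]
        else:
            hits = grp[grp[col] < level]
        if len(hits):
            res[f"{arm}/{band}/{comp}"] = sorted(hits["unit"].tolist())
    return res
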