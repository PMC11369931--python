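"""File-based pipeline: simulate -> connectivity -> mst -> stats.

Each stage consumes the previous stage's declared format and writes its own
under ``<out>/<stage>/``, together with the resolved configuration
(JSON) and a log echo of the parameters that matter for reproducibility
(seed, filter order, FDR level).  Re-running a stage with unchanged inputs
and configuration reproduces identical outputs.

Formats
-------
simulate      per-subject HDF5 (dataset ``data`` (R, E, T), attrs ``fs``),
              ``cohort.csv`` and a ``ground_truth.csv`` sidecar with the
              planted coupling and mean planted envelope correlation per band.
connectivity  per subject and band, HDF5 dataset ``aec`` of shape (E, R, R).
mst           per-epoch 3-column edge-list TSVs plus ``metrics.csv``
              (per-epoch and epoch-averaged rows) and ``cohort_metrics.csv``
              (wide: one row per subject, one column per band x metric).
stats         tidy ``stats.csv`` plus a human-readable ``report.txt`` whose
              layout mirrors the band x metric correlation table.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import stats as stats_mod
from .connectivity import connectivity_stack
from .signal import (DEFAULT_FILTER_ORDER, DEFAULT_PAD_SAMPLES, BandSpec,
                     EpochedTimeSeries, bandpass_filter)
from .synthcohort import CohortSpec, draw_cohort_table, iter_cohort
from .tree import mst_from_matrix, subject_metrics, tree_metrics

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from JSON."""

    out_dir: str = "mstmeg_out"
    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec.test_profile)
    filter_order: int = DEFAULT_FILTER_ORDER
    pad_samples: int = DEFAULT_PAD_SAMPLES
    q: float = stats_mod.DEFAULT_Q

    @property
    def bands(self) -> tuple[BandSpec, ...]:
        return self.cohort.bands

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"]["bands"] = [[b.name, b.low, b.high]
                                for b in self.cohort.bands]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        cohort = d.pop("cohort", {})
        if "bands" in cohort:
            cohort["bands"] = tuple(BandSpec(*b) for b in cohort["bands"])
        return cls(cohort=CohortSpec(**cohort), **d)

    def with_overrides(self, seed: int | None = None, out: str | None = None,
                       band_names: list[str] | None = None) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        if seed is not None:
            cfg.cohort = dataclasses.replace(cfg.cohort, seed=seed)
        if out is not None:
            cfg.out_dir = out
        if band_names is not None:
            chosen = tuple(b for b in cfg.cohort.bands if b.name in band_names)
            missing = set(band_names) - {b.name for b in chosen}
            if missing:
                raise ValueError(f"unknown band name(s): {sorted(missing)}")
            cfg.cohort = dataclasses.replace(cfg.cohort, bands=chosen)
        return cfg


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    (d / "config.json").write_text(cfg.to_json())
    return d


def _log_params(stage: str, cfg: PipelineConfig, out: Path) -> None:
    msg = (f"{stage}: seed={cfg.cohort.seed} filter_order={cfg.filter_order} "
           f"pad={cfg.pad_samples} q={cfg.q} bands="
           f"{[b.name for b in cfg.bands]} out={out}")
    logger.info(msg)
    with open(Path(cfg.out_dir) / "pipeline.log", "a") as fh:
        fh.write(msg + "\n")


def simulate(cfg: PipelineConfig) -> Path:
    """Write per-subject HDF5 signals, cohort CSV and ground-truth sidecar."""
    out = _stage_dir(cfg, "simulate")
    _log_params("simulate", cfg, out)
    table = draw_cohort_table(cfg.cohort)
    truth_rows = []
    for row, ts, truth in iter_cohort(cfg.cohort, return_truth=True):
        path = out / f"{row.subject_id}.h5"
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=ts.data)
            dset.attrs["fs"] = ts.fs
            dset.attrs["region_labels"] = ts.region_labels
        trow = {"subject_id": row.subject_id,
                "coupling_true": row.coupling_true}
        for name, env in truth.items():
            # mean planted pairwise envelope correlation over epochs
            rs = []
            for e in range(env.shape[1]):
                c = np.corrcoef(env[:, e, :])
                iu = np.triu_indices(c.shape[0], 1)
                rs.append(c[iu].mean())
            trow[f"planted_env_corr_{name}"] = float(np.mean(rs))
        truth_rows.append(trow)
    table.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    return out


def _read_subject(path: Path) -> EpochedTimeSeries:
    with h5py.File(path, "r") as f:
        dset = f["data"]
        return EpochedTimeSeries(
            data=dset[()], fs=float(dset.attrs["fs"]),
            region_labels=[str(x) for x in dset.attrs["region_labels"]])


def connectivity(cfg: PipelineConfig) -> Path:
    """Band-filter each subject and write per-epoch AEC-c matrix stacks."""
    sim = Path(cfg.out_dir) / "simulate"
    cohort_csv = sim / "cohort.csv"
    if not cohort_csv.exists():
        raise FileNotFoundError(
            f"missing upstream artifact: {cohort_csv} (run the simulate stage first)")
    out = _stage_dir(cfg, "connectivity")
    _log_params("connectivity", cfg, out)
    table = pd.read_csv(cohort_csv)
    for sid in table["subject_id"]:
        spath = sim / f"{sid}.h5"
        if not spath.exists():
            raise FileNotFoundError(f"missing upstream artifact: {spath}")
        ts = _read_subject(spath)
        for band in cfg.bands:
            filtered = bandpass_filter(ts, band, order=cfg.filter_order,
                                       pad_samples=cfg.pad_samples)
            mats = connectivity_stack(filtered, band=band)
            stack = np.stack([m.values for m in mats])
            with h5py.File(out / f"{sid}_{band.name}.h5", "w") as f:
                dset = f.create_dataset("aec", data=stack)
                dset.attrs["band"] = band.name
                dset.attrs["band_edges"] = [band.low, band.high]
    return out


def mst(cfg: PipelineConfig) -> Path:
    """Per-epoch edge-list TSVs, per-epoch metrics, and the cohort table."""
    conn = Path(cfg.out_dir) / "connectivity"
    sim = Path(cfg.out_dir) / "simulate"
    cohort_csv = sim / "cohort.csv"
    if not cohort_csv.exists():
        raise FileNotFoundError(f"missing upstream artifact: {cohort_csv}")
    out = _stage_dir(cfg, "mst")
    _log_params("mst", cfg, out)
    table = pd.read_csv(cohort_csv)
    metric_rows = []
    wide_rows = []
    for _, row in table.iterrows():
        sid = row.subject_id
        wide = {"subject_id": sid, "group": row.group,
                "biomarker": row.biomarker}
        for band in cfg.bands:
            mpath = conn / f"{sid}_{band.name}.h5"
            if not mpath.exists():
                raise FileNotFoundError(f"missing upstream artifact: {mpath}")
            with h5py.File(mpath, "r") as f:
                stack = f["aec"][()]
            tree_dir = out / "trees" / f"{sid}_{band.name}"
            tree_dir.mkdir(parents=True, exist_ok=True)
            for e in range(stack.shape[0]):
                t = mst_from_matrix(stack[e])
                _write_edge_tsv(tree_dir / f"epoch_{e:03d}.tsv", t)
                tm = tree_metrics(t)
                metric_rows.append(dict(subject_id=sid, band=band.name,
                                        epoch=e, L=tm.L, LF=tm.LF, d=tm.d,
                                        D=tm.D, BCmax=tm.BCmax, TH=tm.TH))
            avg = subject_metrics(list(stack))
            metric_rows.append(dict(subject_id=sid, band=band.name,
                                    epoch="mean", L=avg.L, LF=avg.LF,
                                    d=avg.d, D=avg.D, BCmax=avg.BCmax,
                                    TH=avg.TH))
            wide[stats_mod.metric_column(band.name, "lf")] = avg.LF
            wide[stats_mod.metric_column(band.name, "diameter")] = avg.D
            wide[stats_mod.metric_column(band.name, "th")] = avg.TH
        wide_rows.append(wide)
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(wide_rows).to_csv(out / "cohort_metrics.csv", index=False)
    return out


def _write_edge_tsv(path: Path, tree) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={tree.n_nodes}\n")
        fh.write("node_i\tnode_j\tweight\n")
        for i, j, w in tree.edges:
            fh.write(f"{i}\t{j}\t{w:.10g}\n")


def stats(cfg: PipelineConfig) -> Path:
    """Run the association battery on the cohort metrics table."""
    mst_dir = Path(cfg.out_dir) / "mst"
    metrics_csv = mst_dir / "cohort_metrics.csv"
    if not metrics_csv.exists():
        raise FileNotFoundError(f"missing upstream artifact: {metrics_csv}")
    out = _stage_dir(cfg, "stats")
    _log_params("stats", cfg, out)
    table = pd.read_csv(metrics_csv)
    band_names = tuple(b.name for b in cfg.bands)
    results = stats_mod.run_association_battery(table, bands=band_names, q=cfg.q)
    results.to_csv(out / "stats.csv", index=False)
    (out / "report.txt").write_text(_format_report(results, band_names))
    return out


def _format_report(results: pd.DataFrame, bands: tuple[str, ...]) -> str:
    lines = ["Tree topology vs biomarker: Pearson rho and raw p per cell", ""]
    for family, title in [("whole_sample", "Whole sample"),
                          ("subgroup", "Risk groups")]:
        sub = results[results["family"] == family]
        if sub.empty:
            continue
        lines.append(title)
        for band in bands:
            for _, r in sub[sub["band"] == band].iterrows():
                star = "*" if r["significant"] else " "
                lines.append(
                    f"  {band:>6} {r['metric']:>9} {r['group']:>6}  "
                    f"rho={r['estimate']: .3f}  p={r['p_raw']:.3f} "
                    f"(q={r['q_adj']:.3f}){star}")
        lines.append("")
    comp = results[results["family"] == "group_comparison"]
    if not comp.empty:
        lines.append("Group correlation comparison (one-tailed Fisher r-to-z)")
        for _, r in comp.iterrows():
            lines.append(f"  {r['band']:>6} {r['metric']:>9}  "
                         f"z={r['estimate']: .3f}  p={r['p_raw']:.3f}")
        lines.append("")
    return "\n".join(lines)


def run_all(cfg: PipelineConfig) -> Path:
    simulate(cfg)
    connectivity(cfg)
    mst(cfg)
    return stats(cfg)
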