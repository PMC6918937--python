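"""End-to-end orchestration: synthesis -> rhythms -> MI -> selection -> networks.

The pipeline mirrors the analysis workflow of a fatigue EEG study:

1. generate (or load) the epochs of every (subject, time point, condition)
   cell;
2. decompose each epoch into the five rhythms, accumulate the
   (theta+alpha1+alpha2)/beta fatigue ratio and the per-rhythm MI
   adjacency matrix (one matrix per cell, averaged over epochs);
3. one-way ANOVA on mean MI across time points for every
   (rhythm, condition) pair and select the significant ones (p < 0.05);
4. for each selected pair, build binary networks by threshold sweep and by
   fixed degree, and compute C, L and the small-world index against
   degree-preserving null ensembles;
5. ANOVA the group metric trajectories and write tidy CSV/JSON artifacts.

Every stage writes plain files so stages are independently re-runnable,
and all randomness descends from one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import (
    MIEstimatorConfig,
    WeightedAdjacency,
    adjacency_from_epochs,
    mean_mi,
    write_adjacency_csv,
)
from .design import EpochSet, ExperimentDesign, FatigueTrajectory
from .fatigue_index import band_power, fatigue_ratio
from .io import write_epoch_set_csv
from .network import (
    binarize_by_degree,
    default_thresholds,
    small_world,
    threshold_sweep,
    write_graphml,
    write_pajek,
)
from .preprocess import DEFAULT_BANDS, BandDefinition, decompose
from .stats import RhythmSelection, one_way_anova, pairwise_anova, select_rhythm
from .synthdata import generate_dataset

__all__ = [
    "RunConfig",
    "DatasetTables",
    "analyze_cells",
    "analyze_dataset",
    "network_metrics",
    "metric_anova",
    "run_pipeline",
]

log = logging.getLogger("fatiguenet")

# stream tag for network-stage seeds, disjoint from the generator's streams
_NETWORK_STREAM = 2


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully serialisable configuration of one pipeline run."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign.default)
    trajectory: FatigueTrajectory = field(default_factory=FatigueTrajectory.default)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    mi: MIEstimatorConfig = MIEstimatorConfig()
    thresholds: tuple[float, ...] = field(default_factory=default_thresholds)
    k_values: tuple[float, ...] = (5, 6)
    n_nulls: int = 250
    seed: int = 0
    write_epochs: bool = False
    export_graphs: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        object.__setattr__(self, "k_values", tuple(self.k_values))
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        names = {b.name for b in self.bands}
        for required in ("theta", "alpha1", "alpha2", "beta"):
            if required not in names:
                raise ValueError(f"band set must include {required!r}")
        for band in self.bands:
            band.validate_for(self.design.fs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        if "design" in raw:
            kwargs["design"] = ExperimentDesign.from_dict(raw["design"])
        if "trajectory" in raw:
            kwargs["trajectory"] = FatigueTrajectory.from_dict(raw["trajectory"])
        if "bands" in raw:
            kwargs["bands"] = tuple(
                BandDefinition(b["name"], b["lo"], b["hi"]) for b in raw["bands"]
            )
        if "mi" in raw:
            kwargs["mi"] = MIEstimatorConfig(**raw["mi"])
        net = raw.get("network", {})
        if "thresholds" in net:
            kwargs["thresholds"] = tuple(net["thresholds"])
        if "k_values" in net:
            kwargs["k_values"] = tuple(net["k_values"])
        if "n_nulls" in net:
            kwargs["n_nulls"] = int(net["n_nulls"])
        for key in ("seed", "write_epochs", "export_graphs", "make_plots"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "trajectory": self.trajectory.to_dict(),
            "bands": [{"name": b.name, "lo": b.lo, "hi": b.hi} for b in self.bands],
            "mi": {"n_bins": self.mi.n_bins, "bias_correction": self.mi.bias_correction},
            "network": {
                "thresholds": list(self.thresholds),
                "k_values": list(self.k_values),
                "n_nulls": self.n_nulls,
            },
            "seed": self.seed,
            "write_epochs": self.write_epochs,
            "export_graphs": self.export_graphs,
            "make_plots": self.make_plots,
        }


@dataclass
class DatasetTables:
    """Stage-2 output: fatigue ratios, mean-MI table, per-cell adjacencies."""

    ratios: pd.DataFrame
    mean_mi: pd.DataFrame
    adjacency: dict[tuple[str, str, int, str], WeightedAdjacency]

    def adjacency_for(
        self, rhythm: str, condition: str
    ) -> dict[tuple[int, str], WeightedAdjacency]:
        return {
            (subj, tp): adj
            for (rh, cond, subj, tp), adj in self.adjacency.items()
            if rh == rhythm and cond == condition
        }


def analyze_cells(
    cells: Iterable[tuple[int, str, str, EpochSet]],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    mi_cfg: MIEstimatorConfig = MIEstimatorConfig(),
    epoch_writer=None,
) -> DatasetTables:
    """Rhythm decomposition, fatigue ratio and MI adjacency for each cell."""
    ratio_rows = []
    mi_rows = []
    adjacency = {}
    for subject, tp, cond, epochs in cells:
        if epoch_writer is not None:
            epoch_writer(epochs)
        decomp = decompose(epochs, bands)
        ratio = fatigue_ratio(band_power(decomp))
        ratio_rows.append(
            {"subject": subject, "time_point": tp, "condition": cond, "ratio": ratio}
        )
        for band in bands:
            adj = adjacency_from_epochs(decomp[band.name], mi_cfg)
            adjacency[(band.name, cond, subject, tp)] = adj
            mi_rows.append(
                {
                    "rhythm": band.name,
                    "condition": cond,
                    "subject": subject,
                    "time_point": tp,
                    "mean_mi": mean_mi(adj),
                }
            )
    return DatasetTables(
        ratios=pd.DataFrame(ratio_rows),
        mean_mi=pd.DataFrame(mi_rows),
        adjacency=adjacency,
    )


def analyze_dataset(
    design: ExperimentDesign,
    trajectory: FatigueTrajectory,
    seed: int,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    mi_cfg: MIEstimatorConfig = MIEstimatorConfig(),
    conditions: Optional[Sequence[str]] = None,
    epoch_writer=None,
) -> DatasetTables:
    """Generate the synthetic dataset and run stage 2 on every cell.

    ``conditions`` restricts the analysis to a subset of the design's
    conditions (e.g. only the task state for a targeted network run).
    """
    wanted = tuple(conditions) if conditions is not None else design.conditions
    for cond in wanted:
        if cond not in design.conditions:
            raise KeyError(f"unknown condition {cond!r}")
    cells = (
        cell for cell in generate_dataset(design, trajectory, seed) if cell[2] in wanted
    )
    return analyze_cells(cells, bands=bands, mi_cfg=mi_cfg, epoch_writer=epoch_writer)


def _network_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(_NETWORK_STREAM, *key))
    return int(ss.generate_state(1)[0])


def network_metrics(
    adjacencies: dict[tuple[int, str], WeightedAdjacency],
    time_points: Sequence[str],
    thresholds: Sequence[float],
    k_values: Sequence[float],
    n_nulls: int,
    seed: int,
) -> pd.DataFrame:
    """Small-world metrics per subject and time point, both binarizations.

    Returns a tidy table with one row per (subject, time point, method,
    parameter): method is ``threshold`` (parameter = T) or ``degree``
    (parameter = K).  Thresholds whose graph has isolated nodes carry NaN
    metrics and ``isolated = True``.
    """
    rows = []
    subjects = sorted({s for s, _ in adjacencies})
    tp_index = {tp: i for i, tp in enumerate(time_points)}
    for subject in subjects:
        for tp in time_points:
            adj = adjacencies.get((subject, tp))
            if adj is None:
                raise KeyError(f"missing adjacency for subject {subject} at {tp}")
            base = {"subject": subject, "time_point": tp}
            sweep = threshold_sweep(
                adj,
                thresholds,
                n_nulls=n_nulls,
                seed=_network_seed(seed, subject, tp_index[tp], 0),
            )
            for t, res, iso, m in zip(
                sweep.thresholds, sweep.results, sweep.isolated, sweep.edge_counts
            ):
                row = {
                    **base, "method": "threshold", "param": t, "n_edges": m,
                    "isolated": iso,
                }
                row.update(
                    res.as_dict() if res is not None
                    else {"C": np.nan, "L": np.nan, "C_rand": np.nan,
                          "L_rand": np.nan, "sigma": np.nan,
                          "n_nulls": n_nulls, "disconnected": False}
                )
                rows.append(row)
            for ki, k in enumerate(k_values):
                graph = binarize_by_degree(adj, k)
                res = small_world(
                    graph,
                    n_nulls=n_nulls,
                    seed=_network_seed(seed, subject, tp_index[tp], 1 + ki),
                )
                rows.append(
                    {
                        **base, "method": "degree", "param": k,
                        "n_edges": graph.n_edges,
                        "isolated": bool(graph.isolated_nodes),
                        **res.as_dict(),
                    }
                )
    df = pd.DataFrame(rows)
    df["sigma"] = df["sigma"].astype(float)
    return df


def metric_anova(
    metrics: pd.DataFrame, time_points: Sequence[str], values=("C", "L", "sigma")
) -> pd.DataFrame:
    """One-way ANOVA across time points per (method, parameter, metric)."""
    rows = []
    for (method, param), block in metrics.groupby(["method", "param"]):
        if block[list(values)].isna().any().any():
            continue  # thresholds flagged somewhere: group incomplete
        for value in values:
            groups = [
                block.loc[block["time_point"] == tp, value].to_numpy()
                for tp in time_points
            ]
            if any(g.size < 2 for g in groups):
                continue
            res = one_way_anova(groups)
            rows.append(
                {
                    "method": method, "param": param, "metric": value,
                    "F": res.F, "df_between": res.df_between,
                    "df_within": res.df_within, "p": res.p, "flag": res.flag,
                }
            )
    return pd.DataFrame(rows)


def _pattern_summary(
    tables: DatasetTables,
    metrics_by_pair: dict[tuple[str, str], pd.DataFrame],
    selection: RhythmSelection,
    design: ExperimentDesign,
) -> dict:
    """Group-mean trajectories and the qualitative fatigue-pattern checks."""
    tps = list(design.time_points)
    upto_t3 = tps[: min(4, len(tps))]

    def increasing(series: Sequence[float]) -> bool:
        return all(b > a for a, b in zip(series, series[1:]))

    summary: dict = {"time_points": tps}
    ratio_means = (
        tables.ratios.groupby(["condition", "time_point"])["ratio"].mean()
    )
    summary["fatigue_ratio"] = {
        cond: [float(ratio_means[cond, tp]) for tp in tps]
        for cond in tables.ratios["condition"].unique()
    }
    summary["selected"] = [list(pair) for pair in selection.selected]
    summary["patterns"] = {}
    for (rhythm, cond), metrics in metrics_by_pair.items():
        key = f"{rhythm}/{cond}"
        mi_block = tables.mean_mi.query(
            "rhythm == @rhythm and condition == @cond"
        )
        mi_means = [
            float(mi_block.loc[mi_block["time_point"] == tp, "mean_mi"].mean())
            for tp in tps
        ]
        thr = metrics.query("method == 'threshold' and not isolated")
        valid = (
            thr.groupby("param")["sigma"]
            .count()
            .pipe(lambda s: s[s == s.max()])
            .index
        )
        thr_valid = thr[thr["param"].isin(valid)]
        thr_means = {
            v: [
                float(thr_valid.loc[thr_valid["time_point"] == tp, v].mean())
                for tp in tps
            ]
            for v in ("C", "L", "sigma")
        }
        deg = metrics.query("method == 'degree'")
        deg_means = {
            f"K={param:g}": {
                v: [
                    float(block.loc[block["time_point"] == tp, v].mean())
                    for tp in tps
                ]
                for v in ("C", "L", "sigma")
            }
            for param, block in deg.groupby("param")
        }
        n_t3 = len(upto_t3)
        summary["patterns"][key] = {
            "mean_mi": mi_means,
            "threshold_method": thr_means,
            "degree_method": deg_means,
            "checks": {
                "mean_mi_increasing_to_T3": increasing(mi_means[:n_t3]),
                "C_increasing_to_T3_threshold": increasing(thr_means["C"][:n_t3]),
                "L_decreasing_to_T3_threshold": increasing(thr_means["L"][:n_t3][::-1]),
                "sigma_decreasing_to_T3_threshold": increasing(
                    thr_means["sigma"][:n_t3][::-1]
                ),
                "sigma_decreasing_to_T3_degree": {
                    k: increasing(v["sigma"][:n_t3][::-1]) for k, v in deg_means.items()
                },
                "sigma_all_above_1_degree": {
                    k: all(s > 1 for s in v["sigma"]) for k, v in deg_means.items()
                },
            },
        }
    return summary


def _plot_series(summary: dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tps = summary["time_points"]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cond, series in summary["fatigue_ratio"].items():
        ax.plot(tps, series, marker="o", label=cond)
    ax.set_xlabel("time point")
    ax.set_ylabel(r"$(\theta+\alpha_1+\alpha_2)/\beta$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "fatigue_ratio.png", dpi=120)
    plt.close(fig)

    for key, pat in summary["patterns"].items():
        safe = key.replace("/", "_")
        fig, axes = plt.subplots(1, 4, figsize=(14, 3.0))
        axes[0].plot(tps, pat["mean_mi"], marker="o")
        axes[0].set_title(f"mean MI ({key})")
        for ax, metric in zip(axes[1:], ("C", "L", "sigma")):
            ax.plot(tps, pat["threshold_method"][metric], marker="o", label="threshold")
            for klab, series in pat["degree_method"].items():
                ax.plot(tps, series[metric], marker="s", label=klab)
            ax.set_title(metric)
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"network_{safe}.png", dpi=120)
        plt.close(fig)


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Execute every stage and write per-stage artifacts under ``out_dir``.

    Returns the run directory.  Any stage failure propagates with its
    stage logged; partial outputs are retained for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)

        log.info("stage synth+analyze: %d subjects, %d time points",
                 cfg.design.n_subjects, len(cfg.design.time_points))
        writer = None
        if cfg.write_epochs:
            epochs_dir = out / "epochs"
            writer = lambda es: write_epoch_set_csv(es, epochs_dir)
        tables = analyze_dataset(
            cfg.design, cfg.trajectory, cfg.seed,
            bands=cfg.bands, mi_cfg=cfg.mi, epoch_writer=writer,
        )
        tables.ratios.to_csv(out / "fatigue_ratios.csv", index=False)
        tables.mean_mi.to_csv(out / "mean_mi.csv", index=False)

        log.info("stage stats: rhythm selection")
        if cfg.design.n_subjects < 2:
            log.warning("fewer than two subjects: ANOVA/selection skipped")
            selection = RhythmSelection(results={}, selected=())
        else:
            selection = select_rhythm(tables.mean_mi, cfg.design.time_points)
        selection.to_frame().to_csv(out / "anova_mean_mi.csv", index=False)
        with open(out / "selection.json", "w") as fh:
            json.dump(
                {
                    "selected": [list(p) for p in selection.selected],
                    "alpha": selection.alpha,
                },
                fh, indent=2,
            )
        log.info("selected rhythms: %s", selection.selected)

        adj_dir = out / "adjacency"
        adj_dir.mkdir(exist_ok=True)
        for (rhythm, cond, subj, tp), adj in tables.adjacency.items():
            write_adjacency_csv(
                adj, adj_dir / f"{rhythm}_{cond}_sub{subj:02d}_{tp}.csv"
            )

        metrics_by_pair = {}
        all_metrics = []
        for rhythm, cond in selection.selected:
            log.info("stage network: %s/%s", rhythm, cond)
            metrics = network_metrics(
                tables.adjacency_for(rhythm, cond),
                cfg.design.time_points,
                cfg.thresholds,
                cfg.k_values,
                cfg.n_nulls,
                cfg.seed,
            )
            metrics.insert(0, "rhythm", rhythm)
            metrics.insert(1, "condition", cond)
            metrics_by_pair[(rhythm, cond)] = metrics
            all_metrics.append(metrics)
            metric_anova(metrics, cfg.design.time_points).to_csv(
                out / f"anova_metrics_{rhythm}_{cond}.csv", index=False
            )
            if cfg.export_graphs:
                graph_dir = out / "graphs"
                graph_dir.mkdir(exist_ok=True)
                for (subj, tp), adj in tables.adjacency_for(rhythm, cond).items():
                    for k in cfg.k_values:
                        g = binarize_by_degree(adj, k)
                        stem = f"{rhythm}_{cond}_sub{subj:02d}_{tp}_K{k:g}"
                        write_pajek(g, graph_dir / f"{stem}.net")
                        write_graphml(g, graph_dir / f"{stem}.graphml")
        if all_metrics:
            pd.concat(all_metrics, ignore_index=True).to_csv(
                out / "network_metrics.csv", index=False
            )
        else:
            log.warning("no rhythm/condition pair reached significance; "
                        "network stage skipped")

        if cfg.design.n_subjects >= 2:
            rows = []
            for cond, block in tables.ratios.groupby("condition"):
                groups = [
                    block.loc[block["time_point"] == tp, "ratio"].to_numpy()
                    for tp in cfg.design.time_points
                ]
                pw = pairwise_anova(groups, cfg.design.time_points)
                pw.insert(0, "condition", cond)
                rows.append(pw)
            pd.concat(rows, ignore_index=True).to_csv(
                out / "anova_ratio_pairwise.csv", index=False
            )

        summary = _pattern_summary(tables, metrics_by_pair, selection, cfg.design)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        if cfg.make_plots:
            _plot_series(summary, out)
        log.info("run complete")
        return out
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
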