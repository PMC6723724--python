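"""End-to-end orchestration: filter, normalize, sweep, select, DE.

The sweep runs fuzzy c-means for every cluster number cl = 2..udc on the
cell feature matrix (cells as points, features log2(normalized + 1) per
gene, optionally standardized), scores each partition with the four
validity indices, and TOPSIS-ranks the resulting decision matrix (criteria
FSI, PE, PC, MPC; impacts up/down/up/up) under the calibration-pinned
configuration. The rank-1 cluster number is selected, its crisp labels
feed per-cluster differential expression and marker calling, and
per-cluster coexpression-style network metrics are reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from mofuzz._version import __version__ as _pkg_version
from mofuzz.diffexp import call_markers
from mofuzz.fcm import FcmConfig, FuzzyPartition, crisp_assign, fcm
from mofuzz.normalize import depth_scale, scnorm_normalize
from mofuzz.qc import filter_cells, filter_genes, select_top_variant_genes
from mofuzz.sc_io import CountMatrix, write_table
from mofuzz.topsis import (
    PINNED_P,
    PINNED_VARIANT,
    PINNED_WEIGHTS,
    DecisionMatrix,
    TopsisResult,
    topsis_rank,
)
from mofuzz.validity import ValidityScores, score_partition

logger = logging.getLogger(__name__)

CRITERIA = ["FSI", "PE", "PC", "MPC"]
IMPACTS = ["benefit", "cost", "benefit", "benefit"]


@dataclass
class SweepResult:
    """Per-cluster-number partitions and validity scores, plus selection."""

    udc: int
    partitions: dict[int, FuzzyPartition]
    scores: list[ValidityScores]
    points: np.ndarray
    topsis: TopsisResult | None = None
    selected_cl: int | None = None
    labels: np.ndarray | None = None

    def validity_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_row() for s in self.scores])

    @property
    def selected_partition(self) -> FuzzyPartition:
        if self.selected_cl is None:
            raise ValueError("no selection yet; run select_optimal first")
        return self.partitions[self.selected_cl]


@dataclass
class NetworkMetrics:
    cluster: int
    n_cells: int
    avg_scaled_connectivity: float
    avg_mar: float
    density: float
    avg_correlation: float

    def as_row(self) -> dict:
        return asdict(self)


def cell_features(
    norm: CountMatrix, standardize: bool = False
) -> np.ndarray:
    """Cells x genes feature matrix: log2(normalized + 1), optionally
    z-scored per gene (constant genes are left at zero)."""
    feats = np.log2(norm.counts + 1.0).T
    if standardize:
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        feats = (feats - mu) / np.where(sd > 0, sd, 1.0)
    return feats


def _case_seed(master_seed: int, cl: int) -> int:
    return int(np.random.SeedSequence([master_seed, cl]).generate_state(1)[0] % (2**31))


def sweep_clusterings(
    points: np.ndarray,
    udc: int = 10,
    seed: int = 0,
    m: float = 2.0,
    epsilon: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 5,
) -> SweepResult:
    """Run fuzzy c-means and all four validity indices for cl = 2..udc.

    Each case uses a deterministic seed derived from the master seed and
    its cluster number, so cases can run in any order.
    """
    points = np.asarray(points, dtype=float)
    if udc < 3:
        raise ValueError("udc must be >= 3 (at least two case studies)")
    if udc > points.shape[0]:
        raise ValueError(f"udc={udc} exceeds {points.shape[0]} points")
    partitions: dict[int, FuzzyPartition] = {}
    scores: list[ValidityScores] = []
    for cl in range(2, udc + 1):
        config = FcmConfig(
            cl=cl, m=m, epsilon=epsilon, max_iter=max_iter,
            n_init=n_init, seed=_case_seed(seed, cl),
        )
        try:
            part = fcm(points, config)
            partitions[cl] = part
            scores.append(score_partition(points, part.memberships))
        except Exception as err:  # noqa: BLE001 - reported with its case
            raise RuntimeError(f"sweep failed at cl={cl}: {err}") from err
    return SweepResult(udc=udc, partitions=partitions, scores=scores, points=points)


def select_optimal(
    sweep: SweepResult,
    variant: str = PINNED_VARIANT,
    p: int = PINNED_P,
    weights: tuple[float, ...] = PINNED_WEIGHTS,
) -> SweepResult:
    """TOPSIS-rank the sweep's validity scores and select the rank-1 cl."""
    table = sweep.validity_table()
    dm = DecisionMatrix(
        values=table[CRITERIA].to_numpy(),
        impacts=list(IMPACTS),
        weights=np.asarray(weights, dtype=float),
        alternatives=[f"cl={c}" for c in table["cl"]],
        criteria=list(CRITERIA),
    )
    result = topsis_rank(dm, variant=variant, p=p)
    best_idx = int(np.flatnonzero(result.ranks == 1)[0])
    sweep.topsis = result
    sweep.selected_cl = int(table["cl"].iloc[best_idx])
    sweep.labels = crisp_assign(sweep.partitions[sweep.selected_cl].memberships)
    return sweep


def network_metrics(
    expr: np.ndarray | CountMatrix,
    labels: np.ndarray,
    cluster: int,
) -> NetworkMetrics:
    """Weighted coexpression-style metrics of one cluster's cell-cell
    correlation network.

    Adjacency is |Pearson r| between cell expression profiles (soft
    threshold power 1); connectivity k_i is the row sum over other cells,
    scaled connectivity k_i / max k, MAR_i = sum a^2 / sum a, density the
    mean off-diagonal adjacency, and average correlation the mean of the
    signed r. Pairs with undefined correlation (a constant profile) are
    skipped with a warning.
    """
    values = expr.counts if isinstance(expr, CountMatrix) else np.asarray(expr, float)
    labels = np.asarray(labels)
    cells = values[:, labels == cluster].T  # cells x genes
    n_c = cells.shape[0]
    if n_c < 3:
        raise ValueError(f"cluster {cluster} has {n_c} cells; need >= 3")
    sd = cells.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(
            f"cluster {cluster}: {int((sd == 0).sum())} constant cell profiles; "
            "their pairs are skipped",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(cells)
    np.fill_diagonal(r, np.nan)
    valid = np.isfinite(r)
    a = np.where(valid, np.abs(r), 0.0)
    k = a.sum(axis=1)
    k_max = k.max()
    scaled = k / k_max if k_max > 0 else np.zeros(n_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        mar = np.where(k > 0, (a**2).sum(axis=1) / np.where(k > 0, k, 1.0), 0.0)
    n_pairs = valid.sum()
    density = float(k.sum() / (n_c * (n_c - 1)))
    avg_corr = float(r[valid].mean()) if n_pairs else 0.0
    return NetworkMetrics(
        cluster=int(cluster),
        n_cells=n_c,
        avg_scaled_connectivity=float(scaled.mean()),
        avg_mar=float(mar.mean()),
        density=density,
        avg_correlation=avg_corr,
    )


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with the defaults the tool
    applies to a raw genes x cells count matrix."""

    min_cell_detected: int = 2000
    gene_detected_min: int = 3
    gene_detected_max: int = 500
    top_variant: int = 3000
    variance_on_log1p: bool = False
    skip_normalization: bool = False
    mode_threshold: float = 0.1
    k_max: int = 10
    udc: int = 10
    fuzziness: float = 1.2
    epsilon: float = 1e-6
    max_iter: int = 300
    n_init: int = 5
    standardize: bool = False
    fc_cutoff: float = 2.0
    alpha: float = 0.05
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    m: CountMatrix,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full pipeline on a raw count matrix and write all artifacts.

    Stages: cell filter -> gene filter -> top-variance selection ->
    depth normalization (or plain depth scaling when
    ``skip_normalization``) -> FCM sweep -> TOPSIS selection -> per-cluster
    DE and markers -> network metrics -> 2-D PCA export. Returns the run
    manifest (also written as ``manifest.json``).
    """
    if config is None:
        config = PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    stage = "filter_cells"
    try:
        filtered, cell_report = filter_cells(m, config.min_cell_detected)
        manifest["stages"][stage] = cell_report.to_dict()

        stage = "filter_genes"
        filtered, gene_report = filter_genes(
            filtered, config.gene_detected_min, config.gene_detected_max
        )
        manifest["stages"][stage] = gene_report.to_dict()

        stage = "select_top_variant_genes"
        k = min(config.top_variant, filtered.n_genes)
        filtered, var_report = select_top_variant_genes(
            filtered, k, log1p=config.variance_on_log1p
        )
        manifest["stages"][stage] = var_report.to_dict()

        stage = "normalize"
        if config.skip_normalization:
            norm = depth_scale(filtered)
            manifest["stages"][stage] = {
                "method": "depth_scale", "ablation": True, "converged": True,
            }
        else:
            norm, diag = scnorm_normalize(
                filtered,
                mode_threshold=config.mode_threshold,
                k_max=config.k_max,
            )
            manifest["stages"][stage] = {
                "method": "scnorm_style",
                "ablation": False,
                "chosen_k": diag.chosen_k,
                "converged": bool(diag.converged),
                "max_abs_mode": diag.max_abs_mode,
            }
            write_table(diag.to_frame(), outdir / "slope_diagnostics.tsv")
            manifest["outputs"]["slope_diagnostics"] = "slope_diagnostics.tsv"

        stage = "sweep"
        points = cell_features(norm, standardize=config.standardize)
        udc = min(config.udc, points.shape[0])
        sweep = sweep_clusterings(
            points,
            udc=udc,
            seed=config.seed,
            m=config.fuzziness,
            epsilon=config.epsilon,
            max_iter=config.max_iter,
            n_init=config.n_init,
        )
        manifest["stages"][stage] = {
            "udc": udc,
            "converged": all(p.converged for p in sweep.partitions.values()),
            "cases": {
                cl: {"n_iter": p.n_iter, "converged": bool(p.converged),
                     "objective": p.objective[-1]}
                for cl, p in sweep.partitions.items()
            },
        }
        write_table(sweep.validity_table(), outdir / "validity_table.tsv")
        manifest["outputs"]["validity_table"] = "validity_table.tsv"

        stage = "select"
        sweep = select_optimal(sweep)
        topsis_table = sweep.topsis.to_frame()
        topsis_table.insert(1, "cl", [int(a.split("=")[1]) for a in topsis_table["alternative"]])
        write_table(topsis_table, outdir / "topsis_table.tsv")
        manifest["outputs"]["topsis_table"] = "topsis_table.tsv"
        manifest["stages"][stage] = {
            "selected_cl": sweep.selected_cl,
            "closeness": float(sweep.topsis.closeness.max()),
            "converged": True,
        }
        part = sweep.selected_partition
        memberships = pd.DataFrame(
            part.memberships.T,
            columns=[f"cluster_{j}" for j in range(part.cl)],
        )
        memberships.insert(0, "cell_id", norm.cell_ids)
        write_table(memberships, outdir / "memberships.tsv")
        labels_table = pd.DataFrame(
            {"cell_id": norm.cell_ids, "cluster": sweep.labels}
        )
        write_table(labels_table, outdir / "labels.tsv")
        manifest["outputs"]["memberships"] = "memberships.tsv"
        manifest["outputs"]["labels"] = "labels.tsv"

        stage = "diffexp"
        de_results, markers = call_markers(
            norm, sweep.labels, fc_cutoff=config.fc_cutoff, alpha=config.alpha
        )
        n_degs = {}
        for cluster, de in de_results.items():
            write_table(de.table, outdir / f"de_cluster_{cluster}.tsv")
            write_table(markers[cluster], outdir / f"markers_cluster_{cluster}.tsv")
            manifest["outputs"][f"de_cluster_{cluster}"] = f"de_cluster_{cluster}.tsv"
            manifest["outputs"][f"markers_cluster_{cluster}"] = (
                f"markers_cluster_{cluster}.tsv"
            )
            n_degs[cluster] = int(de.table["is_DEG"].sum())
        manifest["stages"][stage] = {
            "n_degs": n_degs,
            "n_markers": {c: int(len(t)) for c, t in markers.items()},
            "converged": True,
        }

        stage = "network_metrics"
        rows = []
        for cluster in np.unique(sweep.labels):
            if (sweep.labels == cluster).sum() >= 3:
                rows.append(network_metrics(norm, sweep.labels, int(cluster)).as_row())
        net_table = pd.DataFrame(rows)
        write_table(net_table, outdir / "network_metrics.tsv")
        manifest["outputs"]["network_metrics"] = "network_metrics.tsv"
        manifest["stages"][stage] = {"n_clusters": len(rows), "converged": True}

        stage = "pca"
        coords = PCA(n_components=2, random_state=config.seed).fit_transform(points)
        pca_table = pd.DataFrame(
            {"cell_id": norm.cell_ids, "PC1": coords[:, 0], "PC2": coords[:, 1],
             "cluster": sweep.labels}
        )
        write_table(pca_table, outdir / "pca_coords.tsv")
        manifest["outputs"]["pca_coords"] = "pca_coords.tsv"
        manifest["stages"][stage] = {"n_components": 2, "converged": True}
    except Exception as err:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["output_hashes"] = {
        name: _sha256(outdir / fname) for name, fname in manifest["outputs"].items()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
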