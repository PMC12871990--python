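"""End-to-end orchestration: contours -> distances -> clustering/MDS/ROC.

`run` consumes a directory of per-cell contour CSVs (plus a centre table
when the persistence metric is used), computes the requested distance
matrix, clusters it under each requested linkage, scores the purity of the
average-linkage clusters against every linkage tree, embeds the matrix
with cMDS, and — when group labels are available — runs the ROC analysis.
All artefacts are plain text (CSV / JSON / Newick) under the output
directory, and a structured run report records config, versions and a
config hash so identical configs give identical outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import aspect_distance, aspect_ratio, elastic_distance, fourier_descriptor, fourier_distance
from .clustering import LINKAGES, cut, hca, purity
from .contour import (
    Contour,
    NucleusCenter,
    ScaleFactor,
    center_to_microns,
    read_centers,
    read_contour,
    to_microns,
)
from .errors import MalformedInputError, ParameterError
from .evaluation import cmds, roc
from .persistence import diagram_for_cell
from .wasserstein import DistanceMatrix, all_pairs

__all__ = ["RunConfig", "run", "load_population", "metric_matrix"]

METRICS = ("ph", "aspect", "fourier", "elastic")

_RESERVED = {"centers.csv", "centres.csv", "labels.csv"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    input_dir: str
    out_dir: str
    centres: str | None = None
    labels: str | None = None
    metric: str = "ph"
    p: float = 2.0
    fourier_m: int = 10
    resample_n: int = 128
    microns_per_pixel: float = 1.0
    aspect_sqrt: bool = False
    linkages: tuple = LINKAGES
    k: int = 4
    seed: int = 0
    outlier_sd: float = 3.0
    clean: bool = True

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ParameterError(f"metric must be one of {METRICS}, got {self.metric!r}")
        object.__setattr__(self, "linkages", tuple(self.linkages))
        for lk in self.linkages:
            if lk not in LINKAGES:
                raise ParameterError(f"unknown linkage {lk!r}")


def load_population(
    input_dir, centres_path=None, unit: str = "pixel", microns_per_pixel: float = 1.0
):
    """Load all per-cell contour CSVs (and centres) from a directory.

    Sidecar centre files ``<id>.center.csv`` are used when no population
    centre table is given.  With ``microns_per_pixel != 1`` all
    coordinates are converted to microns.
    """
    input_dir = Path(input_dir)
    contours: dict[str, Contour] = {}
    centres: dict[str, NucleusCenter] = {}
    files = sorted(p for p in input_dir.glob("*.csv"))
    table = read_centers(centres_path) if centres_path else {}
    for f in files:
        if f.name.lower() in _RESERVED or f.name.endswith(".center.csv"):
            continue
        c = read_contour(f, unit=unit)
        contours[c.id] = c
        if c.id in table:
            centres[c.id] = table[c.id]
        else:
            sidecar = input_dir / f"{c.id}.center.csv"
            if sidecar.exists():
                xy = pd.read_csv(sidecar, header=None).to_numpy(dtype=float).ravel()
                centres[c.id] = NucleusCenter(float(xy[0]), float(xy[1]))
    if not contours:
        raise MalformedInputError(f"no contour CSVs found in {input_dir}")
    if microns_per_pixel != 1.0:
        s = ScaleFactor(microns_per_pixel)
        contours = {cid: to_microns(c, s) for cid, c in contours.items()}
        centres = {cid: center_to_microns(ctr, s) for cid, ctr in centres.items()}
    return contours, centres


def metric_matrix(contours, centres, config: RunConfig, out_dir: Path | None = None) -> DistanceMatrix:
    """Pairwise distance matrix for the configured metric."""
    ids = sorted(contours)
    if config.metric == "ph":
        missing = [cid for cid in ids if cid not in centres]
        if missing:
            raise MalformedInputError(f"no nucleus centre for cells {missing[:5]!r}")
        diagrams = [diagram_for_cell(contours[cid], centres[cid], clean=config.clean) for cid in ids]
        if out_dir is not None:
            ddir = out_dir / "diagrams"
            ddir.mkdir(parents=True, exist_ok=True)
            for dg in diagrams:
                (ddir / f"{dg.id}.json").write_text(json.dumps(dg.to_dict()))
        return all_pairs(diagrams, config.p)
    n = len(ids)
    M = np.zeros((n, n))
    if config.metric == "aspect":
        ratios = [aspect_ratio(contours[cid], sqrt=config.aspect_sqrt) for cid in ids]
        for i, j in itertools.combinations(range(n), 2):
            M[i, j] = M[j, i] = aspect_distance(ratios[i], ratios[j])
    elif config.metric == "fourier":
        descs = [fourier_descriptor(contours[cid], M=config.fourier_m) for cid in ids]
        for i, j in itertools.combinations(range(n), 2):
            M[i, j] = M[j, i] = fourier_distance(descs[i], descs[j])
    else:  # elastic
        for i, j in itertools.combinations(range(n), 2):
            M[i, j] = M[j, i] = elastic_distance(
                contours[ids[i]], contours[ids[j]], n=config.resample_n
            )
    return DistanceMatrix(tuple(ids), M)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contours, centres = load_population(
        config.input_dir, config.centres, microns_per_pixel=config.microns_per_pixel
    )
    matrix = metric_matrix(contours, centres, config, out_dir=out)
    matrix.to_csv(out / "distmat.csv")

    trees = {}
    for lk in config.linkages:
        tree = hca(matrix, lk)
        trees[lk] = tree
        (out / f"dendrogram_{lk}.nwk").write_text(tree.to_newick() + "\n")
        tree.to_frame().to_csv(out / f"dendrogram_{lk}.csv", index=False)

    base_linkage = "average" if "average" in trees else config.linkages[0]
    assignment = cut(trees[base_linkage], config.k)
    pd.DataFrame(
        sorted(assignment.labels.items()), columns=["id", "cluster"]
    ).to_csv(out / "clusters.csv", index=False)

    groups = assignment.groups()
    table = {
        lk: {name: round(purity(members, trees[lk]), 6) for name, members in groups.items()}
        for lk in config.linkages
    }
    purity_df = pd.DataFrame(table).T.loc[list(config.linkages), sorted(groups)]
    purity_df.index.name = "linkage"
    purity_df.to_csv(out / "purity.csv")

    emb = cmds(matrix, p=2)
    emb_df = pd.DataFrame(
        emb.coordinates, index=list(emb.ids), columns=[f"dim{i + 1}" for i in range(emb.coordinates.shape[1])]
    )
    emb_df.index.name = "id"
    with open(out / "mds.csv", "w") as fh:
        fh.write("# explained: " + ",".join(f"{e:.6f}" for e in emb.explained) + "\n")
        emb_df.to_csv(fh)

    roc_summary = None
    if config.labels:
        labels = pd.read_csv(config.labels).set_index("id")["group"].astype(str).to_dict()
        result = roc(matrix, labels)
        pd.DataFrame({"fpr": result.fpr, "tpr": result.tpr}).to_csv(out / "roc.csv", index=False)
        roc_summary = {"auc": result.auc, "pauc10": result.pauc10}
        (out / "roc.json").write_text(json.dumps(roc_summary, indent=2))

    mean_dist = matrix.values.sum(axis=0) / (len(matrix) - 1)
    cutoff = mean_dist.mean() + config.outlier_sd * mean_dist.std()
    outliers = [cid for cid, md in zip(matrix.ids, mean_dist) if md > cutoff]
    pd.DataFrame({"id": list(matrix.ids), "mean_distance": mean_dist}).to_csv(
        out / "mean_distances.csv", index=False
    )

    report = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_cells": len(contours),
        "metric": config.metric,
        "clusters": {name: len(members) for name, members in groups.items()},
        "purity": {lk: table[lk] for lk in config.linkages},
        "outliers": outliers,
        "roc": roc_summary,
        "versions": _versions(),
    }
    (out / "run.json").write_text(json.dumps(report, indent=2))
    return report


def _versions() -> dict:
    import pandas
    import scipy
    import shapely

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "shapely": shapely.__version__,
    }
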