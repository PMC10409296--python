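"""Synthetic fixtures with known ground truth.

Every generator here is a pure function of its parameters and seed, so
reruns are byte-identical.  The GAF generator writes annotation files whose
exact per-protein knownness under the default weights is computed at
generation time and stored in a JSON sidecar; the screen generator draws
per-gene true effects from a normal bulk contaminated with displaced
outliers, adds additive batch offsets and replicate noise, and records the
complete truth (true effects, outlier labels, batch offsets) alongside the
table; the trace generator emits movement series that round-trip exactly
through the lifespan caller.

Screen defaults are sized like a typical quantitative knockdown screen:
about 200 genes, a handful of replicates each, a few batches with offsets
comparable to the replicate noise, and a small fraction of genes displaced
far from the bulk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    ASPECTS,
    DEFAULT_SCHEME,
    Cluster,
    GoAnnotation,
    write_gaf,
)

from .screens import MovementTrace, ScreenTable

_GO_ASPECTS = tuple(sorted(ASPECTS))


@dataclass
class ScreenTruth:
    """Ground truth behind a generated screen table."""

    mu: np.ndarray  # (J, d) true per-gene effects
    outlier_labels: np.ndarray  # (J,) bool, True for contaminated genes
    gene_ids: tuple[str, ...]
    batch_offsets: np.ndarray  # (n_batches, d)
    batch_ids: tuple[str, ...]
    noise_sd: float
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "mu": self.mu.tolist(),
            "outlier_labels": self.outlier_labels.astype(bool).tolist(),
            "batch_ids": list(self.batch_ids),
            "batch_offsets": self.batch_offsets.tolist(),
            "noise_sd": self.noise_sd,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @property
    def outlier_genes(self) -> set[str]:
        return {g for g, o in zip(self.gene_ids, self.outlier_labels) if o}


def gen_gaf(
    n_proteins: int,
    rates: Mapping[str, float],
    date_range: tuple[date, date] = (date(2000, 1, 1), date(2022, 9, 19)),
    seed: int = 0,
    taxon: str = "9606",
) -> tuple[list[GoAnnotation], dict[str, float]]:
    """Generate annotations with known per-protein scores.

    ``rates`` maps evidence codes to the Poisson mean number of annotations
    per protein carrying that code.  Dates are uniform over ``date_range``.
    Term ids are unique per protein so no record is lost to deduplication.
    Returns the annotations and a sidecar dict of exact expected scores
    under the default weight scheme (all aspects), computed by direct
    summation at generation time.
    """
    for code, rate in rates.items():
        if rate < 0:
            raise ValueError(f"negative annotation rate for {code}")
    rng = np.random.default_rng(seed)
    start, end = date_range
    span = (end - start).days
    annotations: list[GoAnnotation] = []
    expected: dict[str, float] = {}
    for i in range(n_proteins):
        pid = f"UKP{i:05d}"
        term_counter = 0
        score = 0.0
        for code in sorted(rates):
            k = int(rng.poisson(rates[code]))
            for _ in range(k):
                term_counter += 1
                annotations.append(
                    GoAnnotation(
                        protein_id=pid,
                        go_term=f"GO:{term_counter:07d}",
                        aspect=_GO_ASPECTS[int(rng.integers(len(_GO_ASPECTS)))],
                        evidence_code=code,
                        negated=False,
                        first_linked_date=start + timedelta(days=int(rng.integers(span + 1))),
                        reference="PMID:0000000",
                        taxon=taxon,
                        symbol=pid.lower(),
                    )
                )
                score += DEFAULT_SCHEME.weight(code)
        expected[pid] = score
    return annotations, expected


def write_gaf_fixture(
    path: str | Path,
    sidecar_path: str | Path,
    n_proteins: int,
    rates: Mapping[str, float],
    seed: int = 0,
    **kwargs,
) -> tuple[list[GoAnnotation], dict[str, float]]:
    """Generate and write a GAF fixture plus its expected-score sidecar."""
    annotations, expected = gen_gaf(n_proteins, rates, seed=seed, **kwargs)
    write_gaf(annotations, path)
    Path(sidecar_path).write_text(json.dumps(expected, indent=2) + "\n", encoding="utf-8")
    return annotations, expected


def gen_clusters(
    protein_ids: Sequence[str],
    n_clusters: int,
    taxa: Sequence[str] = ("9606", "7227", "10090"),
    seed: int = 0,
) -> tuple[list[Cluster], dict[str, float]]:
    """Partition proteins into clusters with cyclically assigned taxa and a
    synthetic metazoan-presence fraction per cluster (uniform on [0.5, 1])."""
    rng = np.random.default_rng(seed)
    ids = list(protein_ids)
    rng.shuffle(ids)
    groups = np.array_split(np.array(ids), n_clusters)
    clusters = []
    presence = {}
    for k, grp in enumerate(groups):
        cid = f"CLU{k:04d}"
        members = tuple(
            (pid, taxa[m % len(taxa)], pid.lower()) for m, pid in enumerate(grp)
        )
        clusters.append(Cluster(cluster_id=cid, members=members))
        presence[cid] = round(float(rng.uniform(0.5, 1.0)), 3)
    return clusters, presence


def gen_screen(
    J: int = 200,
    d: int = 2,
    bulk_mean: Sequence[float] | float = 0.0,
    bulk_scatter: np.ndarray | float = 1.0,
    contamination_frac: float = 0.05,
    displacement: Sequence[float] | float = 8.0,
    n_batches: int = 4,
    batch_sd: float = 1.0,
    reps_per_gene: int = 5,
    noise_sd: float = 1.0,
    seed: int = 0,
    phenotype_name: str = "synthetic",
) -> tuple[ScreenTable, ScreenTruth]:
    """Generate a screen table from a normal bulk + displaced outliers.

    Bulk genes draw their true effect from N(bulk_mean, bulk_scatter);
    a ``contamination_frac`` subset is additionally displaced by the given
    vector (a scalar is applied equally to every axis).  Replicates are
    assigned to batches cyclically, batch offsets are N(0, batch_sd^2) per
    axis, and replicate noise is N(0, noise_sd^2).
    """
    if not 0.0 <= contamination_frac <= 0.4:
        raise ValueError("contamination_frac must lie in [0, 0.4]")
    if J < 20:
        raise ValueError("need at least 20 genes")
    rng = np.random.default_rng(seed)

    mean = np.broadcast_to(np.atleast_1d(np.asarray(bulk_mean, dtype=float)), (d,)).copy()
    scatter = np.asarray(bulk_scatter, dtype=float)
    if scatter.ndim == 0:
        scatter = float(scatter) * np.eye(d)
    disp = np.broadcast_to(np.atleast_1d(np.asarray(displacement, dtype=float)), (d,)).copy()

    L = np.linalg.cholesky(scatter)
    mu = mean + rng.standard_normal((J, d)) @ L.T
    n_out = int(round(contamination_frac * J))
    labels = np.zeros(J, dtype=bool)
    if n_out:
        which = rng.choice(J, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        mu[which] += signs[:, None] * disp
        labels[which] = True

    gene_ids = tuple(f"gene{j:04d}" for j in range(J))
    batch_ids = tuple(f"batch{b}" for b in range(n_batches))
    batch_offsets = rng.normal(0.0, batch_sd, size=(n_batches, d))

    rows = []
    for j, g in enumerate(gene_ids):
        for r in range(reps_per_gene):
            b = (j + r) % n_batches
            value = mu[j] + batch_offsets[b] + rng.normal(0.0, noise_sd, size=d)
            row = {"gene": g, "batch": batch_ids[b], "replicate": f"r{r}"}
            for a in range(d):
                row[f"value{a + 1}"] = value[a]
            rows.append(row)
    table = ScreenTable(
        pd.DataFrame(rows),
        phenotype_name=phenotype_name,
        axis_labels=tuple(f"value{a + 1}" for a in range(d)),
    )
    truth = ScreenTruth(
        mu=mu,
        outlier_labels=labels,
        gene_ids=gene_ids,
        batch_offsets=batch_offsets,
        batch_ids=batch_ids,
        noise_sd=noise_sd,
        params={
            "J": J, "d": d, "bulk_mean": mean.tolist(),
            "bulk_scatter": scatter.tolist(),
            "contamination_frac": contamination_frac,
            "displacement": disp.tolist(), "n_batches": n_batches,
            "batch_sd": batch_sd, "reps_per_gene": reps_per_gene,
            "noise_sd": noise_sd, "seed": seed,
        },
    )
    return table, truth


def gen_traces(
    lifespans: Sequence[tuple[str, str, float]],
    experiment_length_hours: float,
    movement_scale: float = 1.0,
    interval_hours: float = 1.0,
    seed: int = 0,
) -> list[MovementTrace]:
    """Generate movement traces that round-trip through the lifespan caller.

    ``lifespans`` is a sequence of (fly_id, gene_id, lifespan_hours); each
    trace has strictly positive displacements up to its lifespan frame and
    zeros after, so calling death times at threshold 0 recovers the input
    exactly (a lifespan equal to the experiment length yields a censored
    call).
    """
    n_frames = int(round(experiment_length_hours / interval_hours))
    rng = np.random.default_rng(seed)
    traces = []
    for fly_id, gene_id, lifespan in lifespans:
        if lifespan > experiment_length_hours:
            raise ValueError(f"lifespan for fly {fly_id} exceeds the experiment length")
        n_alive = int(round(lifespan / interval_hours))
        disp = np.zeros(n_frames)
        if n_alive:
            # strictly positive displacements while alive
            disp[:n_alive] = movement_scale * (0.05 + rng.exponential(1.0, size=n_alive))
        traces.append(
            MovementTrace(
                fly_id=str(fly_id),
                gene_id=str(gene_id),
                displacements=tuple(float(x) for x in disp),
                interval_hours=interval_hours,
            )
        )
    return traces
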