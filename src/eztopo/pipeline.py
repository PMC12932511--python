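"""End-to-end orchestration: recordings -> networks -> features -> reports.

The SEEG path treats every contact as a node; the scalp path first maps
sensor data to region space with sLORETA (per band) and treats the
parcellation regions as nodes.  Downstream of the node time series the
two paths are identical: Pearson networks at the absolute threshold,
nodal metrics, paired EZ/NEZ statistics, sub-network densities, and the
patient-grouped classification protocol.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (CVProtocol, balance_classes, nested_group_cv,
                       permutation_test)
from .connectivity import DEFAULT_THRESHOLD, binarize, pcc_matrix
from .metrics import nodal_feature_table, subnetwork_densities
from .signal import decompose_bands, notch
from .simulate import Recording, SimulationConfig, simulate_scalp, simulate_seeg
from .source import (SLORETA, SourceModel, build_lead_field, make_parcellation,
                     make_source_grid, parcellate)
from .stats import aggregate_pairs, density_state_comparison, stat_table

__all__ = [
    "PipelineConfig",
    "RunReport",
    "recording_band_networks",
    "cohort_feature_table",
    "cohort_density_table",
    "run_pipeline",
    "rank_candidate_nodes",
    "default_scalp_source_model",
]


@dataclass
class PipelineConfig:
    """Configuration of a full simulated-cohort run."""

    modality: str = "seeg"
    states: tuple[str, ...] = ("interictal", "ictal")
    n_patients: int = 20
    threshold: float = DEFAULT_THRESHOLD
    apply_notch: bool = False  # synthetic data carry no mains interference
    n_sources: int = 600
    n_regions: int = 148
    aggregator: str = "mean"
    models: tuple[str, ...] = ("svm",)
    preprocessings: tuple[str, ...] = ("none", "log_z")
    n_perm: int = 0
    seed: int = 0
    simulation_overrides: dict = field(default_factory=dict)


@dataclass
class RunReport:
    """All artifacts of one pipeline run, traceable to config + seed."""

    config: PipelineConfig
    stat_tables: dict  # state -> feature-wise Wilcoxon/BH table
    density_table: pd.DataFrame
    density_comparison: Optional[pd.DataFrame]
    classifier_reports: list
    permutation_results: list
    feature_tables: dict  # state -> nodal feature table
    stage_seconds: dict = field(default_factory=dict)


def default_scalp_source_model(n_sources: int = 600, n_regions: int = 148,
                               seed: int = 0) -> SourceModel:
    """16-electrode spherical source model with a k-means parcellation."""
    grid = make_source_grid(n_sources, seed=seed)
    model = build_lead_field(grid=grid)
    model.parcellation = make_parcellation(grid, n_regions=n_regions, seed=seed)
    return model


def _node_series(rec: Recording, source_model: Optional[SourceModel],
                 apply_notch: bool, inv: Optional[SLORETA] = None,
                 mains_hz: float = 50.0):
    """Node time series per band plus node labels and the EZ mask."""
    data = rec.data
    if apply_notch:
        data = notch(data, rec.sampling_rate, mains_hz=mains_hz)
    banded = decompose_bands(data, rec.sampling_rate)
    if rec.modality == "seeg":
        labels = rec.channel_labels
        return {b.band.name: b.data for b in banded}, labels, rec.ez_mask
    if source_model is None:
        raise ValueError("scalp recordings need a source model for the ESI stage")
    if inv is None:
        inv = SLORETA().fit(source_model)
    out = {}
    region_labels = None
    for b in banded:
        power = inv.transform(b.data)
        series, region_labels = parcellate(np.sqrt(power), source_model.parcellation)
        out[b.band.name] = series
    labels = [f"region{int(r)}" for r in region_labels]
    if rec.ez_region_mask is None:
        raise ValueError("scalp recording lacks region-level EZ labels")
    return out, labels, np.asarray(rec.ez_region_mask, dtype=bool)


def recording_band_networks(rec: Recording, threshold: float = DEFAULT_THRESHOLD,
                            source_model: Optional[SourceModel] = None,
                            apply_notch: bool = False,
                            inv: Optional[SLORETA] = None,
                            mains_hz: float = 50.0) -> dict:
    """Band name -> :class:`BinaryNetwork` for one recording."""
    series, labels, ez_mask = _node_series(rec, source_model, apply_notch, inv,
                                           mains_hz)
    nets = {}
    for band, data in series.items():
        conn = pcc_matrix(data, node_labels=labels, band=band, state=rec.state)
        nets[band] = binarize(conn, threshold, ez_mask=ez_mask)
    return nets


def cohort_feature_table(recordings: Sequence[Recording],
                         threshold: float = DEFAULT_THRESHOLD,
                         source_model: Optional[SourceModel] = None,
                         apply_notch: bool = False,
                         mains_hz: float = 50.0) -> pd.DataFrame:
    """Tidy node-level table: ids, labels and the 28 feature columns."""
    inv = SLORETA().fit(source_model) if source_model is not None else None
    frames = []
    for rec in recordings:
        nets = recording_band_networks(rec, threshold, source_model, apply_notch,
                                       inv, mains_hz)
        feats = nodal_feature_table(nets)
        ez_mask = next(iter(nets.values())).ez_mask
        feats.insert(0, "patient_id", rec.patient_id)
        feats.insert(1, "state", rec.state)
        feats.insert(2, "modality", rec.modality)
        feats.insert(4, "ez_label", np.asarray(ez_mask, dtype=bool))
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)


def cohort_density_table(recordings: Sequence[Recording],
                         threshold: float = DEFAULT_THRESHOLD,
                         source_model: Optional[SourceModel] = None,
                         apply_notch: bool = False,
                         mains_hz: float = 50.0) -> pd.DataFrame:
    """Per patient x state x band EZ/NEZ sub-network densities."""
    inv = SLORETA().fit(source_model) if source_model is not None else None
    rows = []
    for rec in recordings:
        nets = recording_band_networks(rec, threshold, source_model, apply_notch,
                                       inv, mains_hz)
        for band, net in nets.items():
            d = subnetwork_densities(net)
            rows.append({"patient_id": rec.patient_id, "state": rec.state,
                         "modality": rec.modality, "band": band,
                         "d_ez": d.d_ez, "d_nez": d.d_nez, "d_cross": d.d_cross,
                         "e_ez": d.e_ez, "e_nez": d.e_nez, "e_cross": d.e_cross,
                         "n_ez": d.n_ez, "n_nez": d.n_nez})
    return pd.DataFrame(rows)


def _simulate_state(config: PipelineConfig, state: str,
                    source_model: Optional[SourceModel]):
    overrides = dict(config.simulation_overrides)
    overrides.update(n_patients=config.n_patients, state=state, seed=config.seed)
    if config.modality == "seeg":
        sim = SimulationConfig(modality="seeg", **overrides)
        return simulate_seeg(sim)
    sim = SimulationConfig.scalp_default(**overrides)
    return simulate_scalp(sim, source_model)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute simulate -> preprocess -> [ESI] -> network -> metrics ->
    stats -> classification for every configured state."""
    t0 = time.perf_counter()
    stage_seconds = {}
    source_model = None
    if config.modality == "scalp":
        source_model = default_scalp_source_model(
            config.n_sources, config.n_regions, seed=config.seed)
        stage_seconds["source_model"] = time.perf_counter() - t0

    feature_tables, stat_tables, density_frames = {}, {}, []
    for state in config.states:
        t = time.perf_counter()
        recs = _simulate_state(config, state, source_model)
        feats = cohort_feature_table(recs, config.threshold, source_model,
                                     config.apply_notch)
        feature_tables[state] = feats
        paired = aggregate_pairs(feats, aggregator=config.aggregator)
        stat_tables[state] = stat_table(paired)
        density_frames.append(cohort_density_table(
            recs, config.threshold, source_model, config.apply_notch))
        stage_seconds[f"state_{state}"] = time.perf_counter() - t

    density_table = pd.concat(density_frames, ignore_index=True)
    density_comparison = None
    if {"ictal", "interictal"} <= set(config.states):
        density_comparison = density_state_comparison(density_table)

    classifier_reports, permutation_results = [], []
    protocol = CVProtocol()
    for state in config.states:
        t = time.perf_counter()
        balanced = balance_classes(feature_tables[state], seed=config.seed)
        for model in config.models:
            for prep in config.preprocessings:
                report = nested_group_cv(balanced, model, protocol, prep,
                                         seed=config.seed)
                report.as_dict()  # validate serializability early
                classifier_reports.append((state, report))
                if config.n_perm > 0:
                    perm = permutation_test(balanced, model, protocol, prep,
                                            n_perm=config.n_perm,
                                            seed=config.seed)
                    permutation_results.append((state, model, prep, perm))
        stage_seconds[f"classify_{state}"] = time.perf_counter() - t

    return RunReport(config=config, stat_tables=stat_tables,
                     density_table=density_table,
                     density_comparison=density_comparison,
                     classifier_reports=classifier_reports,
                     permutation_results=permutation_results,
                     feature_tables=feature_tables,
                     stage_seconds=stage_seconds)


def rank_candidate_nodes(feature_table: pd.DataFrame, scores: np.ndarray,
                         k: Optional[int] = None) -> pd.DataFrame:
    """Rank nodes by EZ probability score (stable sort, descending).

    Returns the identifying columns plus the score; ``k`` larger than
    the node count returns everything with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(feature_table):
        raise ValueError("one score per node row is required")
    out = feature_table[[c for c in ("patient_id", "state", "node", "ez_label")
                         if c in feature_table.columns]].copy()
    out["score"] = scores
    out = out.sort_values("score", ascending=False, kind="mergesort")
    if k is not None:
        if k > len(out):
            warnings.warn(f"k={k} exceeds node count {len(out)}; returning all")
        out = out.head(k)
    return out.reset_index(drop=True)
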