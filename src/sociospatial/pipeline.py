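"""End-to-end orchestration: survey files in, analysis bundle out.

``run_all`` executes the read → vectors → network → leaders/dyads → KDE
sequence and writes seven artifacts into the output directory:

* ``vectors.csv`` — long-format location vectors;
* ``network.graphml`` and ``edges.csv`` — the co-location network;
* ``leaders.csv`` — top leader candidates per community;
* ``dyads.csv`` — support dyads above the score threshold;
* ``kde.asc`` — the density surface (ESRI ASCII raster);
* ``hotspots.geojson`` — ranked hotspot polygons;
* ``run_metadata.json`` — seed, chosen bandwidth, all parameters, record
  counts and every skipped record, so data-quality issues are auditable.

The whole pipeline is a deterministic function of (inputs, config, seed):
re-running with the same configuration produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .activity import VectorConfig, build_location_vectors, write_location_vectors
from .errors import SociospatialError, StageError
from .kde import (
    default_bandwidth,
    estimate_density,
    hotspots,
    hotspots_geojson,
    make_grid,
    point_masses,
    write_esri_ascii,
)
from .network import (
    build_network,
    edges_frame,
    health_measure,
    leaders_table,
    support_dyads,
    write_graphml,
)
from .survey import read_activity_reports, read_gazetteer, read_participants

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "vectors.csv",
    "network.graphml",
    "edges.csv",
    "leaders.csv",
    "dyads.csv",
    "kde.asc",
    "hotspots.geojson",
    "run_metadata.json",
)


@dataclass
class RunConfig:
    """Everything a full run needs. Loadable from YAML via ``from_file``."""

    participants: str
    activity: str
    gazetteer: str
    out_dir: str
    seed: int = 0
    # activity-space parameters
    speed_m_per_min: float = 800.0
    home_jitter_radius_m: float = 0.0
    include_home_in_network: bool = True
    include_home_in_kde: bool = False
    # network parameters
    leader_top_k: int = 2
    leader_decile: float = 0.1
    dyad_measure: str = "isolation"
    dyad_threshold: float = 1.0
    # KDE parameters
    kde_measure: str = "isolation"
    tau: float | None = None
    cell_size: float | None = None
    hotspot_quantile: float = 0.9

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def vector_config(self) -> VectorConfig:
        return VectorConfig(
            speed_m_per_min=self.speed_m_per_min,
            home_jitter_radius_m=self.home_jitter_radius_m,
            include_home_in_network=self.include_home_in_network,
            include_home_in_kde=self.include_home_in_kde,
            seed=self.seed,
        )


@dataclass
class RunResult:
    out_dir: Path
    network: Any
    leaders: Any
    dyads: list
    grid: Any
    spots: list
    metadata: dict


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_all(config: RunConfig) -> RunResult:
    """Run the full analysis; see module docstring for outputs. Any stage
    failure is re-raised as :class:`StageError` naming the stage, and
    partial outputs written before the failure are removed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    try:
        with _stage("read"):
            participants = read_participants(config.participants)
            reports = read_activity_reports(config.activity)
            gazetteer = read_gazetteer(config.gazetteer)

        with _stage("vectors"):
            vcfg = config.vector_config()
            vectors, extended, skipped = build_location_vectors(
                participants, reports, gazetteer, vcfg
            )
            write_location_vectors(vectors, _emit("vectors.csv"))

        with _stage("network"):
            if config.include_home_in_network:
                net_vectors = vectors
            else:
                net_vectors = {
                    pid: v.drop_category(extended, "home") for pid, v in vectors.items()
                }
            net = build_network(net_vectors, participants)
            write_graphml(net, _emit("network.graphml"))
            edges_frame(net).to_csv(_emit("edges.csv"), index=False, float_format="%.17g")

        with _stage("leaders"):
            leaders = leaders_table(
                net, top_k=config.leader_top_k, decile=config.leader_decile
            )
            leaders.to_csv(_emit("leaders.csv"), index=False, float_format="%.10g")

        with _stage("dyads"):
            dyads = support_dyads(
                net, measure=config.dyad_measure, threshold=config.dyad_threshold
            )
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "receiver": d.receiver,
                        "provider": d.provider,
                        "support_score": d.support_score,
                        "measure": d.measure,
                    }
                    for d in dyads
                ],
                columns=["receiver", "provider", "support_score", "measure"],
            ).to_csv(_emit("dyads.csv"), index=False, float_format="%.10g")

        with _stage("kde"):
            hs = {}
            for p in participants:
                try:
                    hs[p.id] = health_measure(p.scores, config.kde_measure)
                except SociospatialError:
                    logger.warning("participant %s: %s measure missing; excluded "
                                   "from density", p.id, config.kde_measure)
            events = point_masses(
                vectors, hs, extended, exclude_home=not config.include_home_in_kde
            )
            tau = config.tau if config.tau is not None else default_bandwidth(events)
            grid_spec = make_grid(events, tau, cell_size=config.cell_size)
            grid = estimate_density(events, grid_spec, tau)
            spots = hotspots(grid, quantile=config.hotspot_quantile)
            write_esri_ascii(grid, _emit("kde.asc"))
            hotspots_geojson(grid, spots, _emit("hotspots.geojson"))

        with _stage("metadata"):
            metadata = {
                "package_version": __version__,
                "config": asdict(config),
                "seed": config.seed,
                "tau_m": tau,
                "grid": {
                    "origin": list(grid.spec.origin),
                    "cell_size_m": grid.spec.cell_size,
                    "ncols": grid.spec.ncols,
                    "nrows": grid.spec.nrows,
                },
                "counts": {
                    "participants": len(participants),
                    "reports": len(reports),
                    "gazetteer_places": len(gazetteer),
                    "location_space": len(extended),
                    "network_edges": net.n_edges,
                    "kde_events": len(events),
                    "hotspots": len(spots),
                    "dyads": len(dyads),
                },
                "skipped_reports": [
                    {
                        "participant_id": r.participant_id,
                        "category": r.category,
                        "travel_bin": list(r.travel_bin),
                        "frequency": r.frequency,
                    }
                    for r in skipped
                ],
            }
            with open(_emit("run_metadata.json"), "w", encoding="utf-8") as fh:
                json.dump(metadata, fh, indent=1, sort_keys=True)
                fh.write("\n")
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    return RunResult(
        out_dir=out,
        network=net,
        leaders=leaders,
        dyads=dyads,
        grid=grid,
        spots=spots,
        metadata=metadata,
    )
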