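"""End-to-end analysis: synthetic tracks -> trips -> UDs -> segregation,
front use and inference.  This is the programmatic counterpart of the
``glacierseg run-all`` command and the workhorse of the recovery checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from . import inference, movement, patch_use, space_use
from .synthetic import Seascape, SimConfig, simulate_seascape, simulate_tracks
from .trajectory import Colony, TripParams, Trip, mann_whitney_u, preprocess_individual


@dataclass
class PipelineResult:
    seascape: Seascape
    trips: list[Trip]
    n_individuals: int
    n_individuals_ud: int
    anosim_global: inference.AnosimResult | None = None
    anosim_pairwise: pd.DataFrame | None = None
    dispersion: tuple[float, float] | None = None
    si: space_use.SegregationMatrix | None = None
    glmm: inference.GlmmResult | None = None
    glmm_distance_ci: tuple[float, float] | None = None
    lrt_distance: tuple[float, int, float] | None = None
    cond_r2: float | None = None
    overdispersion_p: float | None = None
    mrm: inference.MrmResult | None = None
    mann_whitney: tuple[float, float] | None = None
    report: dict = field(default_factory=dict)


def colonies_from_seascape(seascape: Seascape) -> dict[str, Colony]:
    return {
        cid: Colony(id=cid, lon=pos[0], lat=pos[1], size=size)
        for cid, pos, size in zip(
            seascape.colony_ids, seascape.colony_positions, seascape.colony_sizes
        )
    }


def land_polygon_xy(seascape: Seascape) -> shapely.Polygon:
    arr = np.asarray(seascape.land_polygon, dtype=float)
    return shapely.Polygon(arr)  # lon/lat ring; used with lon/lat points


def front_use_data(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate a study and return the tidy trip x front use table only.

    Columns: individual_id, trip_id, front_id, used, distance_km, sex,
    colony.  This is the input of the front-use GLMM; the UD/segregation
    stages are skipped entirely.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 17)
    seascape = simulate_seascape(config)
    fixes, _ = simulate_tracks(config, seascape)
    colonies = colonies_from_seascape(seascape)
    land = land_polygon_xy(seascape)
    trips, colony_of = [], {}
    for ind, grp in fixes.groupby("individual_id", sort=True):
        cid = str(grp["colony_id"].iloc[0])
        colony_of[ind] = cid
        trips.extend(
            t
            for t in preprocess_individual(
                grp.reset_index(drop=True), colonies[cid], land
            )
            if t.complete
        )
    fronts = patch_use.build_fronts(seascape)
    cf_km = patch_use.colony_front_distances(seascape.colony_positions, fronts)
    colony_index = {cid: i for i, cid in enumerate(seascape.colony_ids)}
    table = patch_use.front_use_table(
        trips, fronts, seascape.projection, colony_of, cf_km, colony_index
    )
    sex_of = {
        ind: ("female" if rng.uniform() < 0.5 else "male")
        for ind in sorted(colony_of)
    }
    table["sex"] = table["individual_id"].map(sex_of)
    table["colony"] = table["individual_id"].map(colony_of)
    return table


def run_pipeline(
    config: SimConfig,
    seed: int | None = None,
    n_perm: int = 999,
    params: TripParams = TripParams(),
    model_kinds: tuple[str, ...] = ("IID", "OU", "OUF"),
    cell: float = 500.0,
    narea_threshold: float = movement.NAREA_THRESHOLD,
    with_representativeness: bool = False,
) -> PipelineResult:
    """Simulate a study under ``config`` and run the full analysis.

    ``seed`` (defaults to ``config.seed``) drives every stochastic stage
    downstream of the simulation: sex assignment, permutation engines and
    the dispersion diagnostic.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 17)

    seascape = simulate_seascape(config)
    fixes, truth = simulate_tracks(config, seascape)
    colonies = colonies_from_seascape(seascape)
    proj = seascape.projection
    land = land_polygon_xy(seascape)

    # --- trips -------------------------------------------------------------
    all_trips: list[Trip] = []
    colony_of: dict[str, str] = {}
    for ind, grp in fixes.groupby("individual_id", sort=True):
        cid = str(grp["colony_id"].iloc[0])
        colony_of[ind] = cid
        trips = preprocess_individual(
            grp.reset_index(drop=True), colonies[cid], land, params
        )
        all_trips.extend(trips)
    complete = [t for t in all_trips if t.complete]
    incomplete = [t for t in all_trips if not t.complete]
    mw = None
    if complete and incomplete:
        mw = mann_whitney_u(
            [t.max_range_km(colonies[colony_of[t.individual_id]]) for t in complete],
            [t.max_range_km(colonies[colony_of[t.individual_id]]) for t in incomplete],
        )

    result = PipelineResult(
        seascape=seascape,
        trips=complete,
        n_individuals=len(colony_of),
        n_individuals_ud=0,
        mann_whitney=mw,
    )
    result.report["n_trips_complete"] = len(complete)
    result.report["n_trips_incomplete"] = len(incomplete)

    # --- movement models & UDs --------------------------------------------
    trips_by_ind: dict[str, list[Trip]] = {}
    for t in complete:
        trips_by_ind.setdefault(t.individual_id, []).append(t)

    uds: dict[str, movement.UD] = {}
    fixes_xy: dict[str, np.ndarray] = {}
    trip_counts: dict[str, int] = {}
    selected_kinds: dict[str, str] = {}
    for ind, trips in sorted(trips_by_ind.items()):
        frames = pd.concat([t.fixes for t in trips], ignore_index=True)
        xy = movement.to_local_xy(
            frames["lon"].to_numpy(), frames["lat"].to_numpy(), proj
        )
        tmin = (
            (frames["timestamp"] - frames["timestamp"].iloc[0]).dt.total_seconds()
            / 60.0
        ).to_numpy()
        keep = np.concatenate([[True], np.diff(tmin) > 0])
        xy, tmin = xy[keep], tmin[keep]
        if len(xy) < 10:
            continue
        try:
            models = movement.fit_all_models(xy, tmin, kinds=model_kinds)
            best = movement.select_model(models)
            ud = movement.akde(xy, best, cell=cell, narea_threshold=narea_threshold)
        except (movement.ModelFitError, movement.NAreaError, ValueError):
            continue
        uds[ind] = ud
        fixes_xy[ind] = xy
        trip_counts[ind] = len(trips)
        selected_kinds[ind] = best.kind
    result.n_individuals_ud = len(uds)
    result.report["selected_models"] = selected_kinds

    # --- segregation -------------------------------------------------------
    groups_ok = False
    if len(uds) >= 4:
        si = space_use.segregation_matrix(uds, colony_of)
        result.si = si
        labels = np.asarray(si.labels())
        _, counts = np.unique(labels, return_counts=True)
        groups_ok = len(counts) >= 2 and np.all(counts >= 2)
        if groups_ok:
            result.anosim_global = inference.anosim(
                si.si, labels, n_perm=n_perm, seed=seed + 1
            )
            result.anosim_pairwise = inference.pairwise_anosim(
                si.si, labels, n_perm=n_perm, seed=seed + 2
            )
            try:
                result.dispersion = inference.dispersion_homogeneity(
                    si.si, labels, n_perm=n_perm, seed=seed + 3
                )
            except ValueError:
                result.dispersion = None

    if with_representativeness and uds:
        rep = {}
        for cid in seascape.colony_ids:
            members = {i: u for i, u in uds.items() if colony_of[i] == cid}
            if len(members) >= 3:
                rep[cid] = space_use.representativeness(
                    members,
                    {i: fixes_xy[i] for i in members},
                    weights={i: trip_counts[i] for i in members},
                    seed=seed + 5,
                ).percent
        result.report["representativeness_pct"] = rep

    # --- front use and GLMM ------------------------------------------------
    fronts = patch_use.build_fronts(seascape)
    if fronts and complete:
        cf_km = patch_use.colony_front_distances(
            seascape.colony_positions, fronts
        )
        colony_index = {cid: i for i, cid in enumerate(seascape.colony_ids)}
        table = patch_use.front_use_table(
            complete, fronts, proj, colony_of, cf_km, colony_index
        )
        sex_of = {
            ind: ("female" if rng.uniform() < 0.5 else "male")
            for ind in sorted(colony_of)
        }
        table["sex"] = table["individual_id"].map(sex_of)
        table["colony"] = table["individual_id"].map(colony_of)
        try:
            full = inference.fit_binomial_glmm(
                table, terms=("distance", "sex", "colony")
            )
            null = inference.fit_binomial_glmm(table, terms=("sex", "colony"))
            result.glmm = full
            result.glmm_distance_ci = full.ci("distance_km")
            result.lrt_distance = inference.lrt(null, full)
            result.cond_r2 = inference.conditional_r2(full)
            result.overdispersion_p = inference.overdispersion_check(
                full, n_sim=100, seed=seed + 4
            )
        except (inference.SeparationError, RuntimeError):
            pass

        # --- use profiles and MRM -------------------------------------
        profiles = {}
        for ind, trips in sorted(trips_by_ind.items()):
            rows = np.vstack(
                [patch_use.trip_front_use(t, fronts, proj) for t in trips]
            )
            profiles[ind] = patch_use.use_profile(
                ind, rows, [f.id for f in fronts]
            )
        dh_ids, dh = patch_use.dh_matrix(profiles)
        mrm_ids = [i for i in dh_ids if i in uds]
        if result.si is not None and len(mrm_ids) >= 4:
            pos = {i: k for k, i in enumerate(dh_ids)}
            sel_dh = np.ix_([pos[i] for i in mrm_ids], [pos[i] for i in mrm_ids])
            spos = {i: k for k, i in enumerate(result.si.ids)}
            sel_si = np.ix_([spos[i] for i in mrm_ids], [spos[i] for i in mrm_ids])
            size_mat, sep_mat = inference.build_predictor_matrices(
                mrm_ids, colony_of, colonies, proj
            )
            result.mrm = inference.mrm(
                result.si.si[sel_si],
                {
                    "size": size_mat,
                    "separation": sep_mat,
                    "dh": dh[sel_dh],
                },
                n_perm=n_perm,
                seed=seed + 6,
            )
    return result
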