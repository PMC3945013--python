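"""End-to-end in-silico mapping study.

One *study* = one synthetic atrium + electrode setup, a control simulation
with uniform membrane properties, and a set of simulations with circular
ACh-heterogeneity zones.  For every run the pipeline computes epicardial
unipolar electrograms, balloon-catheter potentials, Tikhonov-reconstructed
virtual endocardial electrograms, activation and ATa maps on both sides of
the wall, epi-endo agreement statistics, and (for zone runs) the distance
between the zone center and the peak of the endocardial delta-ATa map.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import egm_processing as proc
from . import electrogram as eg
from . import geometry as geo
from . import membrane, monodomain, noncontact, registration

__all__ = [
    "StudyConfig",
    "ZoneConfig",
    "GeometryBundle",
    "StudyReport",
    "build_geometry",
    "simulate_run",
    "analyze_run",
    "run_study",
    "desk_config",
    "full_config",
]


# named zone locations: direction from the chamber center.  RAGP sits at
# the SVC-atrial junction, the interatrial (Bachmann) bundles antero-
# superiorly -- both at the margins of the plaque coverage, as in the
# animal preparation; the remaining locations hug the vena-cava rims.
ZONE_DIRECTIONS = {
    "free-wall": (1.0, 0.0, 0.05),
    "free-wall-2": (0.88, -0.40, 0.25),
    "RAGP": (0.65, 0.20, 0.65),
    "RAGP-2": (0.78, 0.38, 0.42),
    "IA": (0.10, 0.75, 0.60),
    "IA-2": (-0.15, 0.85, 0.45),
    "SVC-near": (0.50, 0.28, 0.85),
    "SVC-near-2": (0.20, 0.60, 0.80),
    "IVC-near": (0.45, -0.30, -0.85),
}

# probe sites for contact-vs-noncontact bipolar morphology; the
# coronary-sinus site is excluded from the summary statistic
BIPOLAR_PROBE_SITES = ["SVC-near", "SVC-near-2", "RAGP", "IA", "free-wall",
                       "CS"]
BIPOLAR_EXCLUDED_SITES = ["CS"]


@dataclass
class ZoneConfig:
    location: str              # key of ZONE_DIRECTIONS
    radius: float              # mm, 2-5 when replicating the study design
    ach: float = 0.03          # uM

    def label(self) -> str:
        return f"{self.location}-r{self.radius:g}"


@dataclass
class StudyConfig:
    """Complete configuration of an in-silico mapping study."""

    # geometry
    semi_axes: tuple = (18.0, 16.0, 15.0)
    subdivisions: int = 3
    bem_subdivisions: int = 1   # extra refinement of the inverse surface
    balloon_fill: float = 0.7   # balloon semi-axes as fraction of chamber's
    wall_thickness: float = 1.75
    h: float = 0.5
    # membrane / tissue
    model: str = "surrogate"
    model_params: dict = field(default_factory=dict)
    sigma_l: float = 12.0
    anisotropy: float = 3.0
    beta: float = 2000.0
    # stimulation
    cycle_length: float = 600.0
    stim_amplitude: float = 40.0
    stim_duration: float = 2.0
    max_beats: int = 10
    # zones
    zones: list = field(default_factory=list)
    # processing
    smooth_mm: float = 5.0
    ata_t1: float = 35.0
    ata_t2: float = 300.0
    activation_window: tuple = (0.0, 160.0)
    # inverse problem
    lambda_policy: str = "calibrate"   # or a float as string / number
    lambda_grid: tuple = (-10.0, -1.0, 19)
    # misc
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zones"] = [asdict(z) if isinstance(z, ZoneConfig) else z
                      for z in self.zones]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["zones"] = [ZoneConfig(**z) if isinstance(z, dict) else z
                      for z in d.get("zones", [])]
        for key in ("semi_axes", "activation_window", "lambda_grid"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # output location is not part of the science
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def desk_config(seed: int = 0, **overrides) -> StudyConfig:
    """Desk-scale study: surrogate membrane, h = 0.5 mm, control + 5 zones.

    Zone locations mirror the full study design: ganglionated-plexus and
    interatrial-bundle zones on the free wall plus vein-adjacent zones,
    with radii spanning the 2-5 mm range.
    """
    zones = [
        ZoneConfig("RAGP", 3.0),
        ZoneConfig("IA", 3.0),
        ZoneConfig("SVC-near", 3.0),
        ZoneConfig("SVC-near-2", 5.0),
        ZoneConfig("IVC-near", 2.0),
    ]
    return StudyConfig(zones=zones, seed=seed, **overrides)


def full_config(seed: int = 0, **overrides) -> StudyConfig:
    """Full-fidelity profile: detailed ionic model, h = 0.25 mm,
    control + 7 zone locations x 3 radii = 22 simulations."""
    locations = ["free-wall", "RAGP", "RAGP-2", "IA", "IA-2", "SVC-near",
                 "IVC-near"]
    zones = [ZoneConfig(loc, r) for loc in locations for r in (2.0, 3.0, 5.0)]
    return StudyConfig(
        zones=zones, h=0.25, subdivisions=4, model="crn", seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# geometry bundle
# ---------------------------------------------------------------------------

@dataclass
class GeometryBundle:
    surface: geo.TriSurface          # open anatomical surface (holes cut)
    closed: geo.TriSurface           # closed inverse-problem surface
    lattice: geo.VoxelLattice
    fibers: geo.FiberField
    balloon: geo.BalloonArray
    plaques: geo.ElectrodeArray
    epi_exclude: np.ndarray          # bool mask, appendage epi channels
    san_site: np.ndarray             # stimulus voxel indices
    sampler: geo.SurfaceSampler

    def zone_spec(self, zone: ZoneConfig) -> geo.ZoneSpec:
        """Resolve a named zone onto the mid-wall myocardium."""
        direction = ZONE_DIRECTIONS[zone.location]
        p = geo.surface_point(self.surface, direction)
        _, s, n, _ = self.sampler.nearest(p[None, :])
        center = s[0] + 0.5 * self.lattice.thickness * n[0]
        return geo.ZoneSpec(center=center, radius=zone.radius, ach=zone.ach)

    def probe_node_pair(self, site: str, sep_target: float = 3.5):
        """Two nearby closed-surface nodes bracketing a named probe site.

        The pair axis (the bipolar dipole orientation) is aligned with the
        expected local propagation direction -- the tangential component of
        the vector from the sinus-node region to the site -- which is the
        orientation a contact bipolar catheter is normally given.
        """
        direction = (ZONE_DIRECTIONS[site] if site in ZONE_DIRECTIONS
                     else DEFAULT_SITE_DIRECTIONS[site])
        p = geo.surface_point(self.surface, direction)
        d = np.linalg.norm(self.closed.nodes - p, axis=1)
        a = int(np.argmin(d))
        pa = self.closed.nodes[a]
        san_nodes = self.surface.label_of("SAN")
        san = self.surface.nodes[san_nodes].mean(axis=0)
        _, _, nrm, _ = self.sampler.nearest(pa[None, :])
        prop = pa - san
        prop -= (prop @ nrm[0]) * nrm[0]
        np_ = np.linalg.norm(prop)
        d2 = np.linalg.norm(self.closed.nodes - pa, axis=1)
        cand = np.where((d2 > 1.0) & (d2 < 5.0))[0]
        if len(cand) == 0:
            raise ValueError(f"no partner node near probe site {site}")
        if np_ < 1e-9:
            b = int(cand[np.argmin(np.abs(d2[cand] - sep_target))])
            return a, b
        prop /= np_
        e = (self.closed.nodes[cand] - pa) / d2[cand][:, None]
        align = np.abs(e @ prop)
        score = align - 0.1 * np.abs(d2[cand] - sep_target)
        b = int(cand[np.argmax(score)])
        return a, b


DEFAULT_SITE_DIRECTIONS = {
    "CS": (-0.45, -0.80, -0.50),
}


def build_geometry(cfg: StudyConfig) -> GeometryBundle:
    surface = geo.make_synthetic_atrium(
        semi_axes=cfg.semi_axes, subdivisions=cfg.subdivisions, seed=cfg.seed,
    )
    closed = geo.close_holes(surface)
    for _ in range(cfg.bem_subdivisions):
        # refine the virtual surface toward the device's 2048 channels
        import trimesh

        v, f = trimesh.remesh.subdivide(closed.nodes, closed.triangles)
        closed = geo.TriSurface(v, np.asarray(f, dtype=np.int64))
    sampler = geo.SurfaceSampler(surface, spacing=min(0.5 * cfg.h, 0.5))
    lattice = geo.voxelize_shell(surface, cfg.wall_thickness, cfg.h,
                                 sampler=sampler)
    fibers = geo.assign_fibers(lattice)
    balloon = geo.place_balloon(
        surface, radius=tuple(cfg.balloon_fill * np.asarray(cfg.semi_axes)))
    cps = geo.default_plaque_control_points(surface, cfg.wall_thickness,
                                            sampler=sampler)
    plaques = geo.place_plaques(surface, cps,
                                wall_thickness=cfg.wall_thickness,
                                sampler=sampler)
    # appendage channels: epicardial electrodes over appendage-labeled nodes
    app_nodes = set(surface.label_of("appendage").tolist())
    _, _, _, nearest = sampler.nearest(plaques.positions)
    epi_exclude = np.array([int(n) in app_nodes for n in nearest])

    san_nodes = surface.label_of("SAN")
    if san_nodes.size == 0:
        raise ValueError("geometry lacks a SAN label for the stimulus")
    san_center = surface.nodes[san_nodes].mean(axis=0)
    _, s, n, _ = sampler.nearest(san_center[None, :])
    san_mid = s[0] + 0.5 * cfg.wall_thickness * n[0]
    san_site = monodomain.voxels_near(lattice, san_mid, 2.0)
    if san_site.size == 0:
        raise ValueError("SAN stimulus site contains no myocardial voxels")
    return GeometryBundle(
        surface=surface, closed=closed, lattice=lattice, fibers=fibers,
        balloon=balloon, plaques=plaques, epi_exclude=epi_exclude,
        san_site=san_site, sampler=sampler,
    )


# ---------------------------------------------------------------------------
# per-run simulation and analysis
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    label: str
    epi: eg.EgmSet
    catheter: eg.EgmSet
    endo_direct: eg.EgmSet      # current-source electrograms at the nodes
    virtual: eg.EgmSet              # reconstructed endocardial electrograms
    epi_activation: proc.ActivationMap
    endo_activation: proc.ActivationMap   # smoothed virtual map
    epi_ata: proc.ATaMap
    endo_ata: proc.ATaMap
    zone_center: np.ndarray | None = None
    recording: monodomain.TransmembraneRecording | None = None


def simulate_run(bundle: GeometryBundle, cfg: StudyConfig,
                 zones: list[geo.ZoneSpec]) -> monodomain.TransmembraneRecording:
    model = membrane.get_model(cfg.model, **cfg.model_params)
    tissue = monodomain.TissueParams(
        sigma_l=cfg.sigma_l, anisotropy=cfg.anisotropy, beta=cfg.beta,
    )
    stim = monodomain.StimulusProtocol(
        site=bundle.san_site, cycle_length=cfg.cycle_length,
        amplitude=cfg.stim_amplitude, duration=cfg.stim_duration,
        max_beats=cfg.max_beats,
    )
    return monodomain.run_monodomain(
        bundle.lattice, bundle.fibers, model, tissue, stim, zones=zones,
        seed=cfg.seed,
    )


def compute_egms(bundle: GeometryBundle,
                 recording: monodomain.TransmembraneRecording):
    """Epicardial, catheter and direct endocardial electrograms of a run."""
    im = monodomain.extract_Im(recording)
    points = np.vstack([
        bundle.plaques.positions,
        bundle.balloon.positions,
        bundle.closed.nodes,
    ])
    allsets = eg.unipolar_potentials(recording, points, im=im)
    n_epi = bundle.plaques.n_channels
    n_cat = len(bundle.balloon.positions)
    epi = eg.EgmSet(bundle.plaques.positions, allsets.waveforms[:n_epi],
                    fs=allsets.fs)
    catheter = eg.EgmSet(bundle.balloon.positions,
                         allsets.waveforms[n_epi:n_epi + n_cat],
                         fs=allsets.fs)
    endo = eg.EgmSet(bundle.closed.nodes,
                     allsets.waveforms[n_epi + n_cat:], fs=allsets.fs)
    return epi, catheter, endo


def resolve_lambda(cfg: StudyConfig, tm: noncontact.TransferMatrices,
                   endo_direct: eg.EgmSet, catheter: eg.EgmSet) -> float:
    policy = cfg.lambda_policy
    if policy == "calibrate":
        lo, hi, n = cfg.lambda_grid
        grid = np.logspace(lo, hi, int(n))
        lam, _ = noncontact.calibrate_lambda(endo_direct, catheter,
                                             tm.t_ec, grid)
        return lam
    return float(policy)


def analyze_run(bundle: GeometryBundle, cfg: StudyConfig, label: str,
                recording, tm: noncontact.TransferMatrices,
                zone_center=None, keep_recording: bool = False) -> RunResult:
    epi, catheter, endo_direct = compute_egms(bundle, recording)
    virtual = noncontact.reconstruct(catheter, tm.t_ce,
                                     positions=bundle.closed.nodes)
    win = cfg.activation_window
    epi_act = proc.activation_map(epi, window=win)
    endo_act_raw = proc.activation_map(virtual, window=win)
    endo_act = proc.smooth_map(endo_act_raw, cfg.smooth_mm)
    epi_ata = proc.ata_map(epi, epi_act, cfg.ata_t1, cfg.ata_t2)
    endo_ata = proc.ata_map(virtual, endo_act_raw, cfg.ata_t1, cfg.ata_t2)
    return RunResult(
        label=label, epi=epi, catheter=catheter, endo_direct=endo_direct,
        virtual=virtual, epi_activation=epi_act, endo_activation=endo_act,
        epi_ata=epi_ata, endo_ata=endo_ata, zone_center=zone_center,
        recording=recording if keep_recording else None,
    )


def bipolar_morphology(bundle: GeometryBundle, run: RunResult,
                       sites: list[str] | None = None,
                       excluded: list[str] | None = None):
    """Per-site Pearson r between direct-contact and noncontact bipolar
    electrograms (same node pairs), and the mean over non-excluded sites."""
    sites = sites if sites is not None else BIPOLAR_PROBE_SITES
    excluded = excluded if excluded is not None else BIPOLAR_EXCLUDED_SITES
    rows = []
    for site in sites:
        a, b = bundle.probe_node_pair(site)
        direct = eg.bipolar(run.endo_direct, a, b)
        recon = eg.bipolar(run.virtual, a, b)
        r = float(np.corrcoef(direct, recon)[0, 1])
        rows.append({"site": site, "node_a": a, "node_b": b, "r": r,
                     "excluded": site in excluded})
    df = pd.DataFrame(rows)
    mean_r = float(df.loc[~df["excluded"], "r"].mean())
    return mean_r, df


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    runs: pd.DataFrame
    localization: pd.DataFrame
    pooled: dict
    provenance: dict
    bipolar: pd.DataFrame | None = None

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(out / "runs.csv", index=False,
                         float_format="%.6g")
        self.localization.to_csv(out / "localization.csv", index=False,
                                 float_format="%.6g")
        if self.bipolar is not None:
            self.bipolar.to_csv(out / "bipolar.csv", index=False,
                                float_format="%.6g")
        body = {
            "pooled": self.pooled,
            "provenance": self.provenance,
            "runs": json.loads(self.runs.to_json(orient="records",
                                                 double_precision=6)),
            "localization": json.loads(
                self.localization.to_json(orient="records",
                                          double_precision=6)),
        }
        (out / "report.json").write_text(
            json.dumps(body, indent=1, sort_keys=True))


def run_study(cfg: StudyConfig, progress=None,
              transfer_cache: str | None = None,
              return_details: bool = False):
    """Execute the full study described by ``cfg`` and compile the report.

    Returns the :class:`StudyReport`; with ``return_details=True`` also the
    per-run results, the geometry bundle and the transfer matrices.
    """

    def log(msg):
        if progress:
            progress(msg)

    log("building geometry")
    bundle = build_geometry(cfg)
    tm = _transfer_with_cache(bundle, transfer_cache, log)

    runs = [("control", None)] + [(z.label(), z) for z in cfg.zones]
    results: dict[str, RunResult] = {}
    rows, loc_rows = [], []
    lam = None
    corr = registration.nearest_correspondence(
        bundle.plaques.positions, bundle.closed.nodes,
        exclusions=np.where(bundle.epi_exclude)[0],
    )
    bip_mean, bip_df = None, None
    for label, zone in runs:
        status = "ok"
        try:
            log(f"simulating {label}")
            zspec = bundle.zone_spec(zone) if zone is not None else None
            rec = simulate_run(bundle, cfg,
                               [zspec] if zspec is not None else [])
            if lam is None:
                epi0, cat0, endo0 = compute_egms(bundle, rec)
                lam = resolve_lambda(cfg, tm, endo0, cat0)
                tm.with_inverse(lam)
                log(f"lambda = {lam:.3g}")
            res = analyze_run(
                bundle, cfg, label, rec, tm,
                zone_center=None if zspec is None else zspec.center,
            )
            results[label] = res
            act_r, act_p, act_rms = registration.compare_maps(
                res.epi_activation.values, res.endo_activation.values, corr)
            ata_r, ata_p, ata_rms = registration.compare_maps(
                res.epi_ata.values, res.endo_ata.values, corr)
            rows.append({
                "run": label, "status": status,
                "activation_r": act_r, "activation_p": act_p,
                "activation_rms_ms": act_rms,
                "ata_r": ata_r, "ata_p": ata_p, "ata_rms": ata_rms,
                "n_beats": res.recording.n_beats_run if res.recording
                else np.nan,
                "lambda": lam,
            })
            if label == "control":
                bip_mean, bip_df = bipolar_morphology(bundle, res)
        except Exception as exc:  # partial report with per-run status
            rows.append({"run": label, "status": f"failed: {exc}"})
            continue

    control = results.get("control")
    for label, zone in runs[1:]:
        res = results.get(label)
        if res is None or control is None:
            continue
        dmap = proc.delta_ata(res.endo_ata, control.endo_ata)
        dmap_s = proc.smooth_map(dmap, cfg.smooth_mm)
        try:
            peak = proc.locate_peak(dmap_s, signed="pos")
            dist = float(np.linalg.norm(peak - res.zone_center))
        except ValueError:
            peak, dist = None, np.nan
        loc_rows.append({
            "run": label, "zone_x": res.zone_center[0],
            "zone_y": res.zone_center[1], "zone_z": res.zone_center[2],
            "distance_mm": dist,
        })

    # pooled ATa correlation across every successful run
    pooled_epi, pooled_endo = [], []
    for res in results.values():
        pooled_epi.append(res.epi_ata.values[corr.epi_index])
        pooled_endo.append(res.endo_ata.values[corr.endo_index])
    pooled = {}
    if pooled_epi:
        r, p, rms = registration.compare_maps(
            np.concatenate(pooled_epi), np.concatenate(pooled_endo))
        pooled = {"ata_r": r, "ata_p": p, "ata_rms": rms,
                  "n_points": int(sum(len(x) for x in pooled_epi))}
    if bip_mean is not None:
        pooled["bipolar_mean_r"] = bip_mean

    from . import __version__

    report = StudyReport(
        runs=pd.DataFrame(rows),
        localization=pd.DataFrame(loc_rows),
        pooled=pooled,
        provenance={
            "config_hash": cfg.config_hash(), "seed": cfg.seed,
            "version": __version__,
            "n_voxels": int(bundle.lattice.n_voxels),
            "n_surface_nodes": int(bundle.closed.n_nodes),
        },
        bipolar=bip_df,
    )
    if cfg.out_dir:
        report.save(cfg.out_dir)
    if return_details:
        return report, results, bundle, tm
    return report


def _transfer_with_cache(bundle, cache_dir, log):
    if cache_dir is None:
        log("assembling transfer matrices")
        return noncontact.assemble_forward(bundle.closed, bundle.balloon)
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    probe = noncontact.TransferMatrices(
        o_ec=np.empty(0), s_ec=np.empty(0), o_ee=np.empty(0),
        s_ee=np.empty(0), t_ec=np.empty((0, 0)), surface=bundle.closed,
    )
    key = probe.surface_checksum()
    path = cache / f"transfer_{key}.h5"
    if path.exists():
        log(f"transfer cache hit: {path.name}")
        return noncontact.TransferMatrices.load(path)
    log("assembling transfer matrices (cold cache)")
    tm = noncontact.assemble_forward(bundle.closed, bundle.balloon)
    tm.save(path)
    return tm
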