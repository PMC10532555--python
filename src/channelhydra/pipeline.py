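"""End-to-end analysis pipeline and condition comparison.

``run_analysis`` takes one configuration, runs every analysis stage on one
topology/trajectory pair and writes a report bundle: CSV tables, JSON
summaries, an OpenDX density grid and a checksummed manifest. Bundles
produced with the same inputs and configuration are byte-identical.

``compare_conditions`` contrasts two bundles (e.g. a plain-PC-like and a
cardiolipin-like condition) metric by metric, with moving-block bootstrap
confidence intervals over frames to respect temporal autocorrelation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import hydration as hydration_mod
from . import lipids as lipids_mod
from . import sidechain as sidechain_mod
from . import waterwire as waterwire_mod
from .errors import ComparabilityError, StageError
from .trajio import read_topology, read_trajectory, select

__version__ = "0.1.0"

#: config fields that must match for two bundles to be comparable
_COMPARABILITY_FIELDS = (
    "stride", "hbond_cutoff", "shell_radius", "cavity_link_cutoff",
    "lipid_cutoff", "source_radius", "cavity_region_radius", "grid_spacing",
    "site_prob_threshold", "sp_baseline_deg", "selections",
)


@dataclass
class ChiResidueConfig:
    label: str
    ca: str
    tip: str
    helix: str


@dataclass
class AnalysisConfig:
    topology_path: str
    trajectory_path: str
    output_dir: str
    stride: int = 1

    hbond_cutoff: float = 3.0
    shell_radius: float = 5.0
    cavity_link_cutoff: float = 3.5
    lipid_cutoff: float = 3.0
    source_radius: float = 6.0
    cavity_region_radius: float = 10.0
    grid_spacing: float = 1.0
    site_prob_threshold: float = 0.4

    sp_baseline_deg: float = 5.0
    sp_min_occupancy: float = 0.05
    sp_amplitude_ratio: float = 1.5
    sp_merge_separation_deg: float = 15.0

    bootstrap_seed: int = 0
    bootstrap_block: int = 50
    bootstrap_reps: int = 200

    selections: dict = field(default_factory=dict)
    chi_residues: list = field(default_factory=list)
    contact_pairs: list = field(default_factory=list)

    def validate(self) -> None:
        for name in ("hbond_cutoff", "shell_radius", "cavity_link_cutoff",
                     "lipid_cutoff", "source_radius", "cavity_region_radius",
                     "grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @classmethod
    def default(cls, topology_path, trajectory_path, output_dir,
                **overrides) -> "AnalysisConfig":
        """Configuration matching the synthetic channel system's naming."""
        cfg = cls(
            topology_path=str(topology_path),
            trajectory_path=str(trajectory_path),
            output_dir=str(output_dir),
            selections={
                "significant_residues":
                    "chain A and resid 116 119 144 214 245 252",
                "relay": "chain A and resid 119 214 219 245 252 "
                         "and name ND2 NE2 OD1 OE1",
                "entrance": "chain A and resid 24 132",
                "target": "chain C and resid 61 and name OD1",
                "water": "water",
                "lipid_head": "resname CDL and name P1",
                "protein": "chain A or chain C",
                "density_restrict":
                    "(chain A and resid 119 214 245 252) or "
                    "(chain C and resid 61)",
            },
            chi_residues=[
                dataclasses.asdict(ChiResidueConfig(
                    label="aAsn214",
                    ca="chain A and resid 214 and name CA",
                    tip="chain A and resid 214 and name ND2",
                    helix="chain A and resid 204 to 218 and name CA",
                ))
            ],
            contact_pairs=[
                ["chain A and resid 119", "chain A and resid 245"],
            ],
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class ReportBundle:
    """A completed analysis run: output directory plus its manifest."""

    path: Path
    manifest: dict
    config: dict

    def file(self, name: str) -> Path:
        return self.path / name

    def verify(self) -> None:
        for name, digest in self.manifest["files"].items():
            p = self.path / name
            if not p.exists():
                raise StageError("verify", FileNotFoundError(name))
            if _sha256(p) != digest:
                raise StageError(
                    "verify", ValueError(f"checksum mismatch for {name}"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_bundle(path) -> ReportBundle:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    return ReportBundle(path=path, manifest=manifest,
                        config=manifest["config"])


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every analysis stage and write the report bundle.

    Stages: contacts → side-chain SPs → hydration series → density grid and
    water sites → cavity components → water wire → lipid sites/events. Any
    stage failure aborts with the stage name; files written so far are
    flagged partial in the manifest.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"channelhydra {__version__}",
                 f"config: {json.dumps(dataclasses.asdict(config), sort_keys=True)}"]
    written: list[str] = []
    stage = "load"
    try:
        topo = read_topology(config.topology_path)
        traj = read_trajectory(config.trajectory_path, topo)
        sel = {k: select(topo, expr, label=k)
               for k, expr in config.selections.items()}
        stride = config.stride

        stage = "contacts"
        for expr_a, expr_b in config.contact_pairs:
            sa = select(topo, expr_a)
            sb = select(topo, expr_b)
            series = contacts_mod.min_distance_series(traj, sa, sb, stride)
            stats = contacts_mod.contact_stats(series, config.hbond_cutoff)
            tag = f"contact_{_slug(expr_a)}__{_slug(expr_b)}"
            series.to_csv(outdir / f"{tag}.csv")
            stats.to_json(outdir / f"{tag}.json")
            written += [f"{tag}.csv", f"{tag}.json"]
            log_lines.append(f"{tag}: fraction={stats.fraction_in_contact:.4f}")

        stage = "sidechain_sp"
        for rc in config.chi_residues:
            rc = ChiResidueConfig(**rc) if isinstance(rc, dict) else rc
            series = sidechain_mod.chi_angle_series(
                traj, select(topo, rc.ca), select(topo, rc.tip),
                select(topo, rc.helix), label=rc.label, stride=stride)
            model = sidechain_mod.classify_sps(
                series, config.sp_baseline_deg,
                min_occupancy=config.sp_min_occupancy,
                sp_amplitude_ratio=config.sp_amplitude_ratio,
                merge_separation_deg=config.sp_merge_separation_deg)
            model.assignments_frame(series).to_csv(
                outdir / f"sp_{rc.label}.csv", index=False)
            with open(outdir / f"sp_{rc.label}.json", "w") as fh:
                json.dump(model.to_dict(), fh, indent=1)
            written += [f"sp_{rc.label}.csv", f"sp_{rc.label}.json"]
            log_lines.append(f"sp_{rc.label}: {len(model.sps)} SPs")

        stage = "hydration_series"
        hyd = hydration_mod.hydration_count_series(
            traj, sel["significant_residues"], config.shell_radius, stride)
        hyd.to_csv(outdir / "hydration_series.csv")
        hyd.density_estimate().to_csv(outdir / "hydration_density.csv",
                                      index=False)
        written += ["hydration_series.csv", "hydration_density.csv"]
        log_lines.append(f"hydration: mean={np.mean(hyd.counts):.2f}")

        stage = "density_grid"
        grid = hydration_mod.density_map(
            traj, sel["water"], config.grid_spacing,
            restrict_within=(sel["density_restrict"], config.shell_radius),
            stride=stride)
        grid.write_dx(outdir / "water_density.dx")
        sites = hydration_mod.detect_water_sites(
            grid, traj, config.site_prob_threshold, stride)
        hydration_mod.sites_table(sites).to_csv(outdir / "water_sites.csv",
                                                index=False)
        written += ["water_density.dx", "water_sites.csv"]
        log_lines.append(f"water sites: {len(sites)}")

        stage = "cavity"
        cav = hydration_mod.cavity_components(
            traj, sel["entrance"], config.cavity_region_radius,
            config.cavity_link_cutoff, stride)
        cav.to_csv(outdir / "cavity_components.csv")
        written.append("cavity_components.csv")
        log_lines.append(
            f"cavity: modal components={int(np.bincount(cav.n_components).argmax())}")

        stage = "waterwire"
        summary = waterwire_mod.wire_continuity(
            traj, sel["entrance"], config.source_radius, sel["target"],
            sel["relay"], sel["water"], config.hbond_cutoff, stride)
        waterwire_mod.wire_frames_table(summary).to_csv(
            outdir / "wire_frames.csv", index=False)
        summary.to_json(outdir / "wire_summary.json")
        written += ["wire_frames.csv", "wire_summary.json"]
        log_lines.append(f"wire continuity={summary.continuity_fraction:.4f}")

        stage = "lipids"
        occ = lipids_mod.lipid_contact_occupancy(
            traj, sel["protein"], sel["lipid_head"], config.lipid_cutoff,
            stride)
        occ.to_csv(outdir / "lipid_occupancy.csv", index=False)
        lip_sites = lipids_mod.cluster_binding_sites(occ, traj)
        lipids_mod.sites_json(lip_sites, outdir / "lipid_sites.json")
        events, mean_ret = lipids_mod.residence_events(occ.attrs["contacts"])
        lipids_mod.events_table(events).to_csv(outdir / "lipid_events.csv",
                                               index=False)
        written += ["lipid_occupancy.csv", "lipid_sites.json",
                    "lipid_events.csv"]
        log_lines.append(
            f"lipids: {len(lip_sites)} sites, mean retention {mean_ret:.1f} ps")
    except Exception as exc:
        _write_manifest(outdir, config, written, log_lines, partial=True)
        raise StageError(stage, exc) from exc

    manifest = _write_manifest(outdir, config, written, log_lines,
                               partial=False)
    return ReportBundle(path=outdir, manifest=manifest,
                        config=manifest["config"])


def _slug(expr: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in expr)[:40].strip("_")


def _write_manifest(outdir, config, written, log_lines, partial):
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = {
        "version": __version__,
        "partial": partial,
        "config": dataclasses.asdict(config),
        "files": {name: _sha256(outdir / name) for name in sorted(set(written))
                  if (outdir / name).exists()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# condition comparison


def _block_bootstrap_delta(series_a, series_b, block, reps, rng):
    """Bootstrap CI of mean(B) - mean(A) with moving-block resampling."""
    def resample(x):
        n = len(x)
        if n <= block:
            return x
        starts = rng.integers(0, n - block + 1, size=int(np.ceil(n / block)))
        return np.concatenate([x[s:s + block] for s in starts])[:n]

    deltas = np.empty(reps)
    for r in range(reps):
        deltas[r] = resample(series_b).mean() - resample(series_a).mean()
    return float(np.percentile(deltas, 2.5)), float(np.percentile(deltas, 97.5))


def compare_conditions(bundle_a: ReportBundle, bundle_b: ReportBundle,
                       seed: int | None = None) -> pd.DataFrame:
    """Per-metric deltas (B - A) between two report bundles.

    Frame-resolved metrics (mean hydration count, wire continuity, contact
    fractions) carry 95% moving-block bootstrap confidence intervals; SP
    occupancies are reported as plain deltas. Raises
    :class:`ComparabilityError` when the bundles were produced with
    different selections or cutoffs.
    """
    differing = [
        f for f in _COMPARABILITY_FIELDS
        if bundle_a.config.get(f) != bundle_b.config.get(f)
    ]
    if differing:
        raise ComparabilityError(differing)
    cfg = bundle_a.config
    rng = np.random.default_rng(
        cfg["bootstrap_seed"] if seed is None else seed)
    block = cfg["bootstrap_block"]
    reps = cfg["bootstrap_reps"]

    rows = []

    def add(metric, xa, xb):
        lo, hi = _block_bootstrap_delta(xa, xb, block, reps, rng)
        rows.append({"metric": metric, "value_a": float(np.mean(xa)),
                     "value_b": float(np.mean(xb)),
                     "delta": float(np.mean(xb) - np.mean(xa)),
                     "ci_low": lo, "ci_high": hi})

    ha = pd.read_csv(bundle_a.file("hydration_series.csv"))["n_waters"].to_numpy()
    hb = pd.read_csv(bundle_b.file("hydration_series.csv"))["n_waters"].to_numpy()
    add("mean_hydration_count", ha, hb)

    wa = pd.read_csv(bundle_a.file("wire_frames.csv"))["exists"].to_numpy()
    wb = pd.read_csv(bundle_b.file("wire_frames.csv"))["exists"].to_numpy()
    add("wire_continuity", wa, wb)

    for name in sorted(bundle_a.manifest["files"]):
        if name.startswith("contact_") and name.endswith(".csv"):
            da = pd.read_csv(bundle_a.file(name))["distance_A"].to_numpy()
            db = pd.read_csv(bundle_b.file(name))["distance_A"].to_numpy()
            cutoff = cfg["hbond_cutoff"]
            add(f"contact_fraction[{name[8:-4]}]",
                (da <= cutoff).astype(float), (db <= cutoff).astype(float))

    for name in sorted(bundle_a.manifest["files"]):
        if name.startswith("sp_") and name.endswith(".json"):
            with open(bundle_a.file(name)) as fh:
                ma = json.load(fh)
            with open(bundle_b.file(name)) as fh:
                mb = json.load(fh)
            for k in range(max(len(ma["sps"]), len(mb["sps"]))):
                oa = ma["sps"][k]["occupancy"] if k < len(ma["sps"]) else 0.0
                ob = mb["sps"][k]["occupancy"] if k < len(mb["sps"]) else 0.0
                rows.append({"metric": f"sp_occupancy[{name[3:-5]}:SP{k+1}]",
                             "value_a": oa, "value_b": ob, "delta": ob - oa,
                             "ci_low": np.nan, "ci_high": np.nan})
    return pd.DataFrame(rows)
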