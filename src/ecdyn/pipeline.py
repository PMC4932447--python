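"""End-to-end orchestration: construct -> synthetic trajectory -> analysis.

A single YAML-serialisable :class:`RunConfig` (with an explicit seed — there
is no hidden randomness) drives the full analysis: build the construct,
assign the harmonic network, sample a stationary trajectory, slice the
trailing analysis window into fixed-length segments, and average the
flexibility profile and Cα pair-correlation map across segments; a mean
shortest-distance map of the final segment and optional secondary-structure
occupancy tables complete the report bundle.  Every run writes its resolved
configuration back out so any artifact regenerates from config + seed alone.

Chain-pair views reproduce the convention used when comparing flexibility
profiles of two chains: antiparallel (HT) pairs are plotted with the second
chain's residue axis reversed, and the second axis may be shifted by an
offset; the default offset minimises the mean inter-chain Cα-Cα distance of
the paired residues in the construct geometry.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .construct_builder import ConstructModel, ConstructSpec, assemble_construct
from .ecd_core import (
    CorrelationMap,
    FlexibilityProfile,
    average_descriptors,
    compute_covariance,
    superpose_frames,
)
from .errors import ArgumentError, ConfigError, EcdynError
from .structure_metrics import (
    annotate_regions,
    mean_shortest_distance_map,
    occupancy_report,
    parse_ss_table,
    ss_occupancy,
)
from .synthetic_dynamics import (
    BlockPlan,
    BlockSpec,
    CouplingSpec,
    SimulationConfig,
    model_from_construct,
    simulate,
)
from .traj_model import alpha_synuclein_sequence, select, slice_segments


@dataclass
class AnalysisParams:
    """Segment-averaging and PCA parameters of one run."""

    window: float = 200.0            # ps per segment
    take_last: float = 200.0         # trailing ps analysed
    k_max: int = 20
    pca_selection: str = "heavy"
    descriptor_selection: str = "calpha"
    fit: bool = True


@dataclass
class RunConfig:
    """Fully resolved, serialisable description of one pipeline run."""

    seed: int
    construct: ConstructSpec
    plan: BlockPlan
    simulation: SimulationConfig
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    kT: float = 2.577
    friction: float = 50.0
    ss_table: str | None = None      # optional external SS code table

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "kT": self.kT,
            "friction": self.friction,
            "construct": asdict(self.construct),
            "plan": {
                "k_block": self.plan.k_block,
                "k_linker": self.plan.k_linker,
                "cutoff": self.plan.cutoff,
                "decorate_heavy": self.plan.decorate_heavy,
                "jitter_sigma": self.plan.jitter_sigma,
                "blocks": [asdict(b) for b in self.plan.blocks],
                "couplings": [asdict(c) for c in self.plan.couplings],
            },
            "simulation": {
                "n_frames": self.simulation.n_frames,
                "frame_interval": self.simulation.frame_interval,
                "burn_in_frames": self.simulation.burn_in_frames,
                "method": self.simulation.method,
            },
            "analysis": asdict(self.analysis),
        }
        if self.ss_table:
            d["ss_table"] = self.ss_table
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ConfigError("run configuration must state an explicit seed")
        c = dict(d.get("construct") or {})
        seq = c.pop("sequence", "alpha-synuclein")
        if seq == "alpha-synuclein":
            seq = alpha_synuclein_sequence()
        n_res = c.pop("n_residues", None)
        if n_res:
            seq = seq[: int(n_res)]
        construct = ConstructSpec(
            kind=c.pop("kind", "monomer"), sequence=seq,
            dimer_arrangement=c.pop("arrangement",
                                    c.pop("dimer_arrangement", None)),
            separation=float(c.pop("separation", 14.0)),
            tetramer_base=c.pop("tetramer_base", "HT2"))
        p = dict(d.get("plan") or {})
        blocks = tuple(
            BlockSpec(b["chain"] if "chain" in b else b["chain_id"],
                      int(b["start"]), int(b["stop"]),
                      b.get("role", "rigid-block"))
            for b in p.pop("blocks", []))
        couplings = tuple(
            CouplingSpec(cp["chain_a"], tuple(cp["range_a"]),
                         cp["chain_b"], tuple(cp["range_b"]),
                         float(cp["stiffness"]))
            for cp in p.pop("couplings", []))
        plan = BlockPlan(blocks, couplings,
                         k_block=float(p.pop("k_block", 1000.0)),
                         k_linker=float(p.pop("k_linker", 50.0)),
                         cutoff=float(p.pop("cutoff", 1.0)),
                         decorate_heavy=bool(p.pop("decorate_heavy", False)),
                         jitter_sigma=float(p.pop("jitter_sigma", 0.005)))
        s = dict(d.get("simulation") or {})
        sim = SimulationConfig(
            n_frames=int(s.get("n_frames", 2000)),
            frame_interval=float(s.get("frame_interval", 0.1)),
            burn_in_frames=int(s.get("burn_in_frames", 0)),
            seed=int(d["seed"]),
            method=s.get("method", "exact"))
        a = dict(d.get("analysis") or {})
        analysis = AnalysisParams(
            window=float(a.get("window", 200.0)),
            take_last=float(a.get("take_last", 200.0)),
            k_max=int(a.get("k_max", 20)),
            pca_selection=a.get("pca_selection", "heavy"),
            descriptor_selection=a.get("descriptor_selection", "calpha"),
            fit=bool(a.get("fit", True)))
        return cls(seed=int(d["seed"]), construct=construct, plan=plan,
                   simulation=sim, analysis=analysis,
                   kT=float(d.get("kT", 2.577)),
                   friction=float(d.get("friction", 50.0)),
                   ss_table=d.get("ss_table"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path} is not a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Chain-pair flexibility views
# ---------------------------------------------------------------------------

@dataclass
class ChainPairView:
    """Two chains' flexibility profiles on a common display axis.

    The second chain's residue axis is reversed for HT pairs and shifted by
    ``offset`` display positions; the F values themselves are untouched.
    """

    chain_a: str
    chain_b: str
    residues_a: np.ndarray
    values_a: np.ndarray
    residues_b: np.ndarray        # original residue indices of chain b
    values_b: np.ndarray
    positions_b: np.ndarray       # display positions of chain b residues
    alignment: str
    reversed_b: bool
    offset: int


def _default_offset(construct: ConstructModel, chain_a: str, chain_b: str,
                    reversed_b: bool) -> int:
    """Shift minimising the mean paired Cα-Cα distance in the construct."""
    ca_a = construct.chain_calpha_coords(chain_a)
    ca_b = construct.chain_calpha_coords(chain_b)
    na, nb = len(ca_a), len(ca_b)
    best_s, best_d = 0, np.inf
    for s in range(-(nb - 1), na):
        # display position p pairs chain-a residue p with the chain-b residue
        # whose display position is p
        i = np.arange(1, na + 1)
        j = (nb + 1 - (i - s)) if reversed_b else (i - s)
        ok = (j >= 1) & (j <= nb)
        if ok.sum() < min(3, na, nb):
            continue
        d = float(np.linalg.norm(ca_a[i[ok] - 1] - ca_b[j[ok] - 1],
                                 axis=1).mean())
        if d < best_d - 1e-12:
            best_d, best_s = d, s
    return best_s


def pair_view(flex: FlexibilityProfile, chain_a: str, chain_b: str,
              alignment: str, offset: int | None = None,
              construct: ConstructModel | None = None) -> ChainPairView:
    """Build the paired display of two chains' flexibility profiles.

    ``alignment`` is "HH" (second chain unreversed) or "HT" (reversed).  When
    ``offset`` is None it is derived from ``construct`` geometry; with
    neither given the offset is 0.
    """
    if alignment not in ("HH", "HT"):
        raise ArgumentError(f"unknown alignment label {alignment!r}")
    rev = alignment == "HT"
    res_a, val_a = flex.chain_values(chain_a)
    res_b, val_b = flex.chain_values(chain_b)
    if offset is None:
        offset = _default_offset(construct, chain_a, chain_b, rev) \
            if construct is not None else 0
    nb = len(res_b)
    positions = (nb + 1 - res_b + offset) if rev else (res_b + offset)
    return ChainPairView(chain_a, chain_b, res_a, val_a, res_b, val_b,
                         positions, alignment, rev, int(offset))


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def _save_matrix_tsv(path: Path, mat: np.ndarray, labels: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, mat):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _heatmap(path: Path, mat: np.ndarray, labels, title: str, cbar: str,
             chain_of_row: list[str], vmax: float | None = None) -> float:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.max(mat)) if vmax is None else vmax
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(mat, origin="lower", cmap="jet", vmin=0.0, vmax=vmax,
                   interpolation="nearest")
    # chain marker bars: boundaries between chains partition the quadrants
    bounds = [i for i in range(1, len(chain_of_row))
              if chain_of_row[i] != chain_of_row[i - 1]]
    for b in bounds:
        ax.axhline(b - 0.5, color="k", lw=0.8)
        ax.axvline(b - 0.5, color="k", lw=0.8)
    ax.set_title(title)
    ax.set_xlabel("residue (all chains)")
    ax.set_ylabel("residue (all chains)")
    fig.colorbar(im, ax=ax, label=cbar)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return vmax


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write the report bundle.

    Deterministic given the config's seed.  Returns a dict with the in-memory
    results (construct, flexibility, correlation, distance map, pair views)
    and the paths of every written artifact.  Stage failures are re-raised
    with the stage name and the config hash attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    results: dict = {}
    chash = config.config_hash()

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                stages[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and isinstance(exc, EcdynError):
                    raise type(exc)(
                        f"[stage {name}, config {chash}] {exc}") from exc
        return _Timer()

    with stage("construct"):
        construct = assemble_construct(config.construct)
        results["construct"] = construct

    with stage("network"):
        net = model_from_construct(construct, config.plan, kT=config.kT,
                                   friction=config.friction)

    with stage("simulate"):
        traj = simulate(net, config.simulation)

    with stage("segment"):
        ap = config.analysis
        segments = slice_segments(traj, ap.window, ap.take_last)
        pca_sel = select(traj, ap.pca_selection)
        desc_sel = select(traj, ap.descriptor_selection)

    with stage("descriptors"):
        flex = average_descriptors(segments, pca_sel, ap.k_max,
                                   "flexibility", fit=ap.fit)
        corr = average_descriptors(segments, pca_sel, ap.k_max, "correlation",
                                   fit=ap.fit, descriptor_selection=desc_sel)
        spectra = []
        for seg in segments:
            s = superpose_frames(seg, "segment-mean", pca_sel) if ap.fit \
                else seg
            spectra.append(compute_covariance(s, pca_sel).eigenvalues)
        mean_spectrum = np.mean(spectra, axis=0)
        results["flexibility"], results["correlation"] = flex, corr
        results["mean_spectrum"] = mean_spectrum

    with stage("distance_map"):
        dmap = mean_shortest_distance_map(segments[-1], pca_sel)
        results["distance_map"] = dmap

    with stage("pair_views"):
        views = {}
        for (a, b), al in construct.alignment_table.items():
            views[(a, b)] = pair_view(flex, a, b, al, construct=construct)
        results["pair_views"] = views

    if config.ss_table:
        with stage("ss_occupancy"):
            tl = parse_ss_table(config.ss_table,
                                frame_interval=config.simulation.frame_interval)
            occ = annotate_regions(ss_occupancy(tl))
            results["occupancy"] = occ

    with stage("report"):
        # flexibility profile TSV
        p = outdir / "flexibility.tsv"
        with open(p, "w") as fh:
            fh.write("chain\tresidue\tresidue_name\tmean_F\tsd_F\n")
            for i, a in enumerate(flex.atoms):
                sd = flex.sd[i] if flex.sd is not None else 0.0
                fh.write(f"{a.chain_id}\t{a.residue_index}\t{a.residue_name}"
                         f"\t{flex.values[i]:.10g}\t{sd:.10g}\n")
        artifacts["flexibility"] = str(p)

        labels = [f"{c}:{r}" for c, r in corr.residue_labels()]
        chain_rows = [c for c, _ in corr.residue_labels()]
        p = outdir / "correlation_map.tsv"
        _save_matrix_tsv(p, corr.matrix, labels)
        artifacts["correlation_map"] = str(p)
        vmax = _heatmap(outdir / "correlation_map.png", corr.matrix, labels,
                        "Average pair correlations d_ij", "d_ij", chain_rows)
        artifacts["correlation_map_png"] = str(outdir / "correlation_map.png")

        dlab = [f"{c}:{r}" for c, r, _ in dmap.residues]
        dchain = [c for c, _, _ in dmap.residues]
        p = outdir / "distance_map.tsv"
        _save_matrix_tsv(p, dmap.matrix, dlab)
        artifacts["distance_map"] = str(p)
        _heatmap(outdir / "distance_map.png", dmap.matrix, dlab,
                 "Mean shortest distance map", "distance (nm)", dchain)
        artifacts["distance_map_png"] = str(outdir / "distance_map.png")

        p = outdir / "eigen_spectrum.tsv"
        with open(p, "w") as fh:
            fh.write("component\tmean_eigenvalue_nm2\n")
            for k, v in enumerate(mean_spectrum, 1):
                fh.write(f"{k}\t{v:.10g}\n")
        artifacts["eigen_spectrum"] = str(p)

        for (a, b), v in views.items():
            p = outdir / f"pair_view_{a}{b}.tsv"
            with open(p, "w") as fh:
                fh.write("# chains %s,%s alignment=%s reversed=%s offset=%d\n"
                         % (a, b, v.alignment, v.reversed_b, v.offset))
                fh.write("chain\tresidue\tdisplay_position\tF\n")
                for r, val in zip(v.residues_a, v.values_a):
                    fh.write(f"{a}\t{r}\t{r}\t{val:.10g}\n")
                for r, pos, val in zip(v.residues_b, v.positions_b,
                                       v.values_b):
                    fh.write(f"{b}\t{r}\t{pos}\t{val:.10g}\n")
            artifacts[f"pair_view_{a}{b}"] = str(p)

        if "occupancy" in results:
            p = outdir / "ss_occupancy.tsv"
            occupancy_report(results["occupancy"]).to_csv(p, sep="\t",
                                                          index=False)
            artifacts["ss_occupancy"] = str(p)

        config.to_yaml(outdir / "resolved_config.yaml")
        artifacts["resolved_config"] = str(outdir / "resolved_config.yaml")

        meta = {
            "config_hash": chash,
            "seed": config.seed,
            "ecdyn_version": __version__,
            "numpy_version": np.__version__,
            "stage_seconds": stages,
            "colour_scale": {"d_ij_vmax": vmax},
            "n_segments": len(segments),
            "n_atoms": traj.n_atoms,
        }
        p = outdir / "run_metadata.json"
        p.write_text(json.dumps(meta, indent=2, sort_keys=True))
        artifacts["run_metadata"] = str(p)

    missing = [k for k, v in artifacts.items() if not Path(v).exists()]
    if missing:
        raise ConfigError(f"declared outputs missing: {missing}")
    results["artifacts"] = artifacts
    results["stage_seconds"] = stages
    return results
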