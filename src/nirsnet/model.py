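"""Model/Results interface over the full connectome pipeline.

:class:`ConnectomeModel` holds a preprocessed cohort (one hemoglobin time
series per subject) and the analysis configuration; :meth:`ConnectomeModel.fit`
runs correlation → group averaging → sparsity sweep → metrics → null
ensembles → hubs and returns a :class:`ConnectomeResults` carrying the
estimates, their null-model uncertainties, diagnostics and a ``summary()``
table. Construction from raw optical recordings or directly from a
synthetic cohort specification is provided by classmethods; plotting and
serialisation hang off the results object.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from . import nullmodels as NM
from .hubs import HubProfile, MetricCurve, curve_auc, identify_hubs
from .netbuild import (
    BinaryNetwork,
    CorrelationMatrix,
    SparsityGrid,
    correlation_matrix,
    group_mean,
    sparsity_sweep,
    threshold_at_sparsity,
)
from .preprocess import (
    BeerLambertSpec,
    FilterSpec,
    HemoglobinTimeSeries,
    QCReport,
    run_preprocess,
)

__all__ = ["RunConfig", "ConnectomeModel", "ConnectomeResults", "per_subject_metric_auc"]

NODAL_METRICS = ("degree", "efficiency", "betweenness")


@dataclass(frozen=True)
class RunConfig:
    """Resolved, fully serialisable configuration of one fit."""

    contrast: str = "oxy"
    grid_start: float = 0.01
    grid_stop: float = 0.99
    grid_step: float = 0.01
    n_random: int = 100
    swap_factor: float = 10.0
    seed: int = 0
    null_step: int = 5  # null ensembles every null_step-th grid point
    smallworld_band: tuple[float, float] = (0.1, 0.4)
    reference_sparsity: float = 0.1
    modularity_method: str = "deterministic"
    partition_method: str = "multistart"  # module readout at reference S
    partition_restarts: int = 10
    compute_nulls: bool = True
    individual: bool = False

    def grid(self) -> SparsityGrid:
        return SparsityGrid.from_range(self.grid_start, self.grid_stop, self.grid_step)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class ConnectomeModel:
    """A cohort of hemoglobin time series ready for network analysis.

    Parameters
    ----------
    cohort : sequence of HemoglobinTimeSeries
        One preprocessed recording per subject, identical channel order.
    contrast : {'oxy', 'deoxy', 'total'}
        Which hemoglobin contrast the networks are built from.
    """

    def __init__(
        self,
        cohort: Sequence[HemoglobinTimeSeries],
        contrast: str = "oxy",
        qc: list[QCReport] | None = None,
        ground_truth: dict | None = None,
    ) -> None:
        cohort = list(cohort)
        if not cohort:
            raise ValueError("empty cohort")
        ids = cohort[0].channel_ids
        for ts in cohort[1:]:
            if ts.channel_ids != ids:
                raise ValueError("all subjects must share the channel order")
        self.cohort = cohort
        self.contrast = contrast
        self.channel_ids = ids
        self.qc = qc
        self.ground_truth = ground_truth

    # ------------------------------------------------------------- builders
    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence,
        contrast: str = "oxy",
        discard_s: float = 120.0,
        filter_spec: FilterSpec | None = None,
        bl_spec: BeerLambertSpec | None = None,
        ground_truth: dict | None = None,
    ) -> "ConnectomeModel":
        """Preprocess raw two-wavelength recordings into a model."""
        cohort, qcs = [], []
        for rec in recordings:
            ts, qc = run_preprocess(
                rec.od, rec.fs, channel_ids=rec.channel_ids,
                discard_s=discard_s, filter_spec=filter_spec, bl_spec=bl_spec,
            )
            cohort.append(ts)
            qcs.append(qc)
        return cls(cohort, contrast=contrast, qc=qcs, ground_truth=ground_truth)

    @classmethod
    def from_synthetic(cls, spec=None, contrast: str = "oxy") -> "ConnectomeModel":
        """Generate a synthetic cohort and preprocess it."""
        from .synthetic import CohortSpec, generate_cohort

        spec = spec or CohortSpec()
        cohort = generate_cohort(spec)
        return cls.from_recordings(
            cohort.recordings, contrast=contrast, ground_truth=cohort.ground_truth
        )

    @property
    def n_subjects(self) -> int:
        return len(self.cohort)

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    # ------------------------------------------------------------------ fit
    def fit(self, config: RunConfig | None = None, **overrides) -> "ConnectomeResults":
        """Run the pipeline under ``config`` (keyword overrides accepted)."""
        if config is None:
            config = RunConfig(contrast=self.contrast, **overrides)
        elif overrides:
            config = RunConfig(**{**config.to_dict(), **overrides})
        grid = config.grid()

        subject_corrs = [
            correlation_matrix(ts, contrast=config.contrast) for ts in self.cohort
        ]
        group = group_mean(subject_corrs)
        networks = sparsity_sweep(group, grid)

        rows, nodal = [], {m: [] for m in NODAL_METRICS}
        for net in networks:
            gm, nm = M.compute_all(
                net, modularity_method=config.modularity_method, seed=config.seed
            )
            row = gm.as_dict()
            row["S"] = net.sparsity
            row["frac_disconnected"] = gm.frac_disconnected_pairs
            row["K"] = net.K
            row["threshold"] = net.threshold
            row["n_ties"] = net.n_ties
            rows.append(row)
            for m in NODAL_METRICS:
                nodal[m].append(nm.as_dict()[m])
        global_curves = pd.DataFrame(rows).set_index("S")
        nodal_curves = {
            m: MetricCurve(grid=grid, values=np.asarray(v, dtype=float), metric_name=m)
            for m, v in nodal.items()
        }

        auc = {m: curve_auc(c) for m, c in nodal_curves.items()}
        hub_profile = identify_hubs(auc)

        # module readout: seeded best-of-restarts for the highest-Q partition;
        # the metric curves and null comparisons use the fast deterministic
        # optimizer consistently on both the real and the null side
        ref_net = threshold_at_sparsity(group, config.reference_sparsity)
        partition = M.modularity_partition(
            ref_net, method=config.partition_method, seed=config.seed,
            n_restarts=config.partition_restarts,
        )

        nulls = None
        if config.compute_nulls:
            nulls = self._null_analysis(networks, grid, config)

        individual = None
        if config.individual:
            individual = [sparsity_sweep(c, grid) for c in subject_corrs]

        return ConnectomeResults(
            model=self,
            config=config,
            grid=grid,
            subject_corrs=subject_corrs,
            group_corr=group,
            networks=networks,
            global_curves=global_curves,
            nodal_curves=nodal_curves,
            hub_profile=hub_profile,
            partition=partition,
            nulls=nulls,
            individual_networks=individual,
        )

    def _null_analysis(
        self, networks: list[BinaryNetwork], grid: SparsityGrid, config: RunConfig
    ) -> dict:
        """Per-sparsity null ensembles on a subsampled grid: z per metric,
        γ/λ curves, significance ranges, small-world verdict in band."""
        idx = list(range(0, len(networks), config.null_step))
        s_sub = np.array([networks[i].sparsity for i in idx])
        z = {m: [] for m in M.GLOBAL_METRIC_NAMES}
        mu = {m: [] for m in M.GLOBAL_METRIC_NAMES}
        sigma = {m: [] for m in M.GLOBAL_METRIC_NAMES}
        gammas, lams = [], []
        ss = np.random.SeedSequence(config.seed)
        ens_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(idx))]
        for j, i in enumerate(idx):
            net = networks[i]
            ens = NM.build_ensemble(
                net, n_random=config.n_random, swap_factor=config.swap_factor,
                seed=ens_seeds[j], modularity_method=config.modularity_method,
            )
            gm = M.compute_global(net, modularity_method=config.modularity_method)
            for m in M.GLOBAL_METRIC_NAMES:
                cmp = NM.compare(getattr(gm, m), ens, m)
                z[m].append(cmp.z)
                mu[m].append(cmp.mu_rand)
                sigma[m].append(cmp.sigma_rand)
            g, l, _ = NM.normalized_smallworld(gm, ens)
            gammas.append(g)
            lams.append(l)
        gammas, lams = np.asarray(gammas), np.asarray(lams)
        band = config.smallworld_band
        in_band = (s_sub >= band[0] - 1e-9) & (s_sub <= band[1] + 1e-9)
        small_world = bool(
            in_band.any()
            and np.all(gammas[in_band] > 1)
            and np.all(np.abs(lams[in_band] - 1) <= 0.1)
        )
        return {
            "s": s_sub,
            "z": {m: np.asarray(v) for m, v in z.items()},
            "mu": {m: np.asarray(v) for m, v in mu.items()},
            "sigma": {m: np.asarray(v) for m, v in sigma.items()},
            "gamma": gammas,
            "lambda": lams,
            "significance": {
                m: NM.significance_range(s_sub, np.asarray(z[m]))
                for m in M.GLOBAL_METRIC_NAMES
            },
            "small_world_in_band": small_world,
        }


class ConnectomeResults:
    """Fitted connectome: curves, null comparisons, hubs and modules."""

    def __init__(
        self,
        model: ConnectomeModel,
        config: RunConfig,
        grid: SparsityGrid,
        subject_corrs: list[CorrelationMatrix],
        group_corr: CorrelationMatrix,
        networks: list[BinaryNetwork],
        global_curves: pd.DataFrame,
        nodal_curves: dict[str, MetricCurve],
        hub_profile: HubProfile,
        partition: M.ModulePartition,
        nulls: dict | None,
        individual_networks=None,
    ) -> None:
        self.model = model
        self.config = config
        self.grid = grid
        self.subject_corrs = subject_corrs
        self.group_corr = group_corr
        self.networks = networks
        self.global_curves = global_curves
        self.nodal_curves = nodal_curves
        self.hub_profile = hub_profile
        self.partition = partition
        self.nulls = nulls
        self.individual_networks = individual_networks

    # ------------------------------------------------------------ accessors
    def network_at(self, S: float) -> BinaryNetwork:
        s = np.asarray(self.grid.as_array())
        i = int(np.argmin(np.abs(s - S)))
        return self.networks[i]

    def hub_channels(self, which: str = "consensus") -> list[str]:
        sets = {
            "consensus": self.hub_profile.consensus,
            "union": self.hub_profile.union,
        }
        return [self.model.channel_ids[i] for i in sorted(sets[which])]

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        cfg = self.config
        lines = []
        add = lines.append
        rule = "=" * 72
        add(rule)
        add("Resting-state fNIRS functional connectome")
        add(rule)
        add(
            f"Subjects: {self.model.n_subjects}    Channels: {self.model.n_channels}"
            f"    Contrast: {cfg.contrast}"
        )
        add(
            f"Sparsity grid: {cfg.grid_start}..{cfg.grid_stop} step {cfg.grid_step}"
            f"    Null replicates: {cfg.n_random if cfg.compute_nulls else 0}"
        )
        add(f"Config hash: {cfg.hash}    Seed: {cfg.seed}")
        add("-" * 72)
        ref = self.network_at(cfg.reference_sparsity)
        row = self.global_curves.loc[ref.sparsity]
        add(f"At reference sparsity S = {ref.sparsity:.2f} (K = {ref.K} edges):")
        add(
            f"  Cp = {row['Cp']:.4f}   Lp = {row['Lp']:.4f}   "
            f"Eglob = {row['Eglob']:.4f}   Eloc = {row['Eloc']:.4f}"
        )
        add(f"  beta = {row['beta']:.4f}   Q = {row['Q']:.4f}")
        add(
            f"  Modules at S = {ref.sparsity:.2f}: {self.partition.n_modules} "
            f"(Q = {self.partition.Q:.4f}, {self.partition.method})"
        )
        if self.nulls is not None:
            band = cfg.smallworld_band
            s = self.nulls["s"]
            in_band = (s >= band[0] - 1e-9) & (s <= band[1] + 1e-9)
            if in_band.any():
                g = self.nulls["gamma"][in_band]
                l = self.nulls["lambda"][in_band]
                add(
                    f"  Small-world over S in [{band[0]}, {band[1]}]: "
                    f"gamma = {np.nanmean(g):.3f}, lambda = {np.nanmean(l):.3f} "
                    f"-> {'YES' if self.nulls['small_world_in_band'] else 'no'}"
                )
            for m in ("Cp", "Q"):
                for iv in self.nulls["significance"][m]:
                    add(
                        f"  {m} significant vs null over {iv.s_lo:.2f} <= S <= "
                        f"{iv.s_hi:.2f} (mean z = {iv.mean_z:.2f})"
                    )
        add("-" * 72)
        add(f"Hubs (mean + 1 SD on AUC over sparsity):")
        for m in NODAL_METRICS:
            chs = [self.model.channel_ids[i] for i in sorted(self.hub_profile.hub_sets[m])]
            add(f"  {m:<12} {', '.join(chs) if chs else '(none)'}")
        add(f"  consensus    {', '.join(self.hub_channels()) or '(none)'}")
        add(rule)
        return "\n".join(lines)

    # ------------------------------------------------------------- plotting
    def plot_metric_curves(self, metrics=("Cp", "Lp", "Eglob", "Eloc", "beta", "Q"), axes=None):
        """Global metric profiles along the sparsity grid."""
        import matplotlib.pyplot as plt

        if axes is None:
            fig, axes = plt.subplots(2, 3, figsize=(12, 6), constrained_layout=True)
        axes = np.asarray(axes).ravel()
        s = self.global_curves.index.to_numpy()
        for ax, m in zip(axes, metrics):
            ax.plot(s, self.global_curves[m].to_numpy(), lw=1.5)
            ax.set_xlabel("sparsity S")
            ax.set_ylabel(m)
        return axes[0].figure

    # ---------------------------------------------------------------- export
    def save(self, outdir: str | Path) -> Path:
        """Machine-readable results bundle (delimited text + JSON); every
        artifact embeds the config hash and the channel order."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "config_hash": self.config.hash,
            "channel_ids": self.model.channel_ids,
            "n_subjects": self.model.n_subjects,
        }
        (outdir / "config.json").write_text(json.dumps(meta, indent=2))
        header = "\t".join(self.model.channel_ids)
        np.savetxt(
            outdir / "group_correlation.tsv", self.group_corr.values,
            delimiter="\t", header=f"# config={self.config.hash}\n{header}", comments="",
        )
        self.global_curves.to_csv(outdir / "global_curves.tsv", sep="\t")
        hubs = {
            "config_hash": self.config.hash,
            "channel_ids": self.model.channel_ids,
            "auc": {m: v.tolist() for m, v in self.hub_profile.auc.items()},
            "normalized": {m: v.tolist() for m, v in self.hub_profile.normalized.items()},
            "hub_sets": {m: sorted(v) for m, v in self.hub_profile.hub_sets.items()},
            "union": sorted(self.hub_profile.union),
            "consensus": sorted(self.hub_profile.consensus),
        }
        (outdir / "hubs.json").write_text(json.dumps(hubs, indent=2))
        part = {
            "config_hash": self.config.hash,
            "labels": self.partition.labels.tolist(),
            "Q": self.partition.Q,
            "method": self.partition.method,
            "n_modules": self.partition.n_modules,
        }
        (outdir / "partition.json").write_text(json.dumps(part, indent=2))
        if self.nulls is not None:
            nd = {
                "config_hash": self.config.hash,
                "s": self.nulls["s"].tolist(),
                "z": {m: v.tolist() for m, v in self.nulls["z"].items()},
                "mu": {m: v.tolist() for m, v in self.nulls["mu"].items()},
                "sigma": {m: v.tolist() for m, v in self.nulls["sigma"].items()},
                "gamma": self.nulls["gamma"].tolist(),
                "lambda": self.nulls["lambda"].tolist(),
                "small_world_in_band": self.nulls["small_world_in_band"],
                "significance": {
                    m: [
                        {"s_lo": iv.s_lo, "s_hi": iv.s_hi, "mean_z": iv.mean_z}
                        for iv in ivs
                    ]
                    for m, ivs in self.nulls["significance"].items()
                },
            }
            (outdir / "nulls.json").write_text(json.dumps(nd, indent=2))
        if self.model.qc is not None:
            qc = [q.to_dict() for q in self.model.qc]
            (outdir / "qc.json").write_text(json.dumps(qc, indent=2))
        return outdir


def per_subject_metric_auc(
    cohort: Sequence[HemoglobinTimeSeries],
    contrast: str,
    grid: SparsityGrid,
    metrics: tuple[str, ...] = ("Cp", "Lp", "Eglob", "Eloc", "beta", "Q"),
    modularity_method: str = "deterministic",
) -> pd.DataFrame:
    """Per-subject AUC-over-sparsity of each global metric, one contrast.

    The subject × metric table feeding the cross-contrast repeated-measures
    comparison (:func:`nirsnet.repro.contrast_anova`).
    """
    rows = []
    s = grid.as_array()
    for ts in cohort:
        mat = correlation_matrix(ts, contrast=contrast)
        nets = sparsity_sweep(mat, grid)
        curves = {m: [] for m in metrics}
        for net in nets:
            gm = M.compute_global(net, include=metrics, modularity_method=modularity_method)
            for m in metrics:
                curves[m].append(getattr(gm, m))
        row = {}
        for m in metrics:
            v = np.asarray(curves[m], dtype=float)
            ok = np.isfinite(v)
            if ok.sum() < 2:
                row[m] = float("nan")
            elif ok.all():
                row[m] = float(np.trapezoid(v, s))
            else:
                row[m] = float(
                    np.trapezoid(v[ok], s[ok]) * (s[-1] - s[0]) / (s[ok][-1] - s[ok][0])
                )
        rows.append(row)
    return pd.DataFrame(rows)
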