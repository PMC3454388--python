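"""Synthetic resting-state fNIRS cohorts with known ground truth.

Emulates the study conditions the pipeline targets — 15 subjects × 46
channels × 10 min at 25 Hz — with a planted connectivity structure carrying
all three hallmarks of resting-state connectomes: five modules (13/12/8/8/5
channels, mirroring typical whole-head module sizes), one connector-hub
channel whose between-module coupling is raised to the within-module level,
and a small-world pattern. The planted structure is realised as a *blueprint
network*: the channel pairs forming a modular, hub-bridged graph at the
blueprint sparsity receive strong correlations (mean ``r_within``), every
other pair draws from a continuous background tail (mean ``r_between``), and
the resulting target matrix is projected to the nearest unit-diagonal PSD
correlation matrix. A uniform block covariance cannot serve here: thresholded
at sparse levels it produces isolated cliques, not the connected small-world
topology real group matrices yield. Deoxy-Hb is anti-correlated with oxy-Hb,
and the usual nuisance terms are added: slow drift (<0.005 Hz), cardiac
(~1 Hz), respiratory (~0.3 Hz) and optional motion spikes. Hemodynamic signal is synthesised inside the
0.01–0.08 Hz band so the analysis band-pass transmits it essentially
unchanged, which separates filter testing from signal generation.

Everything is deterministic under a seed; per-subject seeds derive from
the cohort seed via numpy's SeedSequence spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

from .netbuild import BinaryNetwork
from .preprocess import BeerLambertSpec, beer_lambert_forward

__all__ = [
    "GroundTruthSpec",
    "NuisanceSpec",
    "CohortSpec",
    "RawRecording",
    "Cohort",
    "build_modular_covariance",
    "ground_truth_network",
    "ground_truth_matrix",
    "simulate_subject",
    "generate_cohort",
    "toy_graph",
    "default_partition",
]

#: Five planted module sizes over 46 channels.
DEFAULT_MODULE_SIZES = (13, 12, 8, 8, 5)


def default_partition(n_channels: int = 46) -> tuple[int, ...]:
    """Module label per channel: five blocks sized 13/12/8/8/5 for 46
    channels, else near-equal fifths."""
    if n_channels == sum(DEFAULT_MODULE_SIZES):
        sizes = DEFAULT_MODULE_SIZES
    else:
        base, extra = divmod(n_channels, 5)
        sizes = tuple(base + (1 if i < extra else 0) for i in range(5))
    labels = []
    for m, s in enumerate(sizes, start=1):
        labels.extend([m] * s)
    return tuple(labels)


@dataclass(frozen=True)
class GroundTruthSpec:
    """Planted connectivity structure of a synthetic cohort.

    ``r_within`` is the mean correlation on blueprint (planted-network)
    pairs, ``r_between`` the mean of the continuous background tail;
    ``hub_degree`` is the connector hub's target degree (its neighbours
    are spread round-robin over all five modules) and ``r_hub`` the mean
    strength of its couplings — strong enough to rank far above the
    background, slightly below ``r_within`` so the near-uniform hub row
    does not break positive semi-definiteness; the blueprint's edge count
    matches ``blueprint_sparsity``. Pair strengths spread by
    ``sd_edge`` (blueprint) and ``sd_background`` (background), giving the
    continuous correlation spectrum real group matrices show;
    ``node_strength_sd`` spreads per-channel background coupling strengths,
    reproducing the heterogeneous nodal centralities of real connectomes
    (without it every non-hub channel would be statistically exchangeable
    and nodal-metric profiles would carry no stable signal);
    ``within_background_boost`` raises same-module background couplings
    above the cross-module level, so edges added at denser thresholds keep
    concentrating inside modules — the distance-decay transitivity real
    correlation matrices show, and the reason their clustering stays above
    degree-matched chance at every sparsity.
    """

    n_channels: int = 46
    partition: tuple[int, ...] = field(default_factory=default_partition)
    r_within: float = 0.6
    r_between: float = 0.16
    hub_channels: tuple[int, ...] = (0,)
    seed: int = 0
    hub_degree: int = 33
    r_hub: float = 0.5
    sd_edge: float = 0.03
    sd_background: float = 0.05
    node_strength_sd: float = 0.05
    within_background_boost: float = 0.06
    n_bridges: int = 5
    blueprint_sparsity: float = 0.1

    def __post_init__(self) -> None:
        part = tuple(int(x) for x in self.partition)
        object.__setattr__(self, "partition", part)
        object.__setattr__(self, "hub_channels", tuple(int(h) for h in self.hub_channels))
        if len(part) != self.n_channels:
            raise ValueError("partition must assign a module label to every channel")
        if not (0.0 <= self.r_between < self.r_within < 1.0):
            raise ValueError("need 0 <= r_between < r_within < 1")
        if any(not (0 <= h < self.n_channels) for h in self.hub_channels):
            raise ValueError("hub channel index out of range")
        if not (0.0 < self.blueprint_sparsity < 1.0):
            raise ValueError("blueprint_sparsity must lie in (0, 1)")
        # the implied target matrix must be realisable: PSD projection may
        # not distort any pair target by more than 0.35
        ground_truth_matrix(self, _check=True)


@dataclass(frozen=True)
class NuisanceSpec:
    """Relative amplitudes (in units of the hemodynamic signal sd) and
    frequencies of the nuisance terms added before the optical forward
    model."""

    drift_amp: float = 1.0
    cardiac_hz: float = 1.0
    resp_hz: float = 0.3
    nuisance_amp: float = 0.5
    spike_rate: float = 0.0  # spikes per minute
    spike_amp: float = 5.0

    def __post_init__(self) -> None:
        if min(self.drift_amp, self.nuisance_amp, self.spike_rate, self.spike_amp) < 0:
            raise ValueError("amplitudes and rates must be non-negative")

    def validate_against_fs(self, fs: float) -> None:
        if max(self.cardiac_hz, self.resp_hz) >= fs / 2:
            raise ValueError("nuisance frequencies must be below Nyquist")


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: who, how long, at what rate, with what truth.

    ``jitter_sd`` is the between-subject spread of the correlation targets.
    Its default (0.10) is calibrated so that split-half reliability across
    subjects sits clearly below split-half reliability over time, the
    ordering real resting-state cohorts show; a much smaller value would
    leave both dominated by sampling noise (band-limited signals carry only
    ~2·B·T effective samples) and the ordering would degenerate to a coin
    flip.
    """

    n_subjects: int = 15
    duration: float = 600.0  # seconds
    fs: float = 25.0
    noise: NuisanceSpec = field(default_factory=NuisanceSpec)
    truth: GroundTruthSpec = field(default_factory=GroundTruthSpec)
    hemo_amp: float = 1e-3  # mM, sd of the oxy-Hb signal (~1 µM)
    kappa: float = 0.5  # deoxy = −κ·oxy + scaled independent noise
    jitter_sd: float = 0.10  # per-subject sd on correlation targets
    signal_band: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration × fs must be an integer number of samples")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not (0.0 <= self.kappa < 1.0):
            raise ValueError("kappa must lie in [0, 1)")
        self.noise.validate_against_fs(self.fs)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class RawRecording:
    """Two-wavelength optical-density series for one subject."""

    od: np.ndarray  # (2, n_channels, n_samples)
    fs: float
    channel_ids: list[str]
    wavelengths: tuple[float, float] = (690.0, 830.0)
    subject_id: str = "sub-01"

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]

    def write_text(self, directory: str | Path) -> list[Path]:
        """One delimited file per wavelength: samples as rows, header row of
        channel IDs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for w, wl in enumerate(self.wavelengths):
            p = directory / f"{self.subject_id}_od{int(wl)}.tsv"
            header = "\t".join(self.channel_ids)
            np.savetxt(p, self.od[w].T, delimiter="\t", header=header, comments="")
            paths.append(p)
        return paths


@dataclass
class Cohort:
    """Subject recordings plus the serialisable ground-truth record."""

    spec: CohortSpec
    recordings: list[RawRecording]
    subject_seeds: list[int]

    @property
    def ground_truth(self) -> dict:
        t = self.spec.truth
        return {
            "partition": list(t.partition),
            "hub_channels": list(t.hub_channels),
            "r_within": t.r_within,
            "r_between": t.r_between,
            "seed": t.seed,
            "subject_seeds": list(self.subject_seeds),
            "blueprint_edges": ground_truth_network(t).edges(),
        }

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rec in self.recordings:
            rec.write_text(directory)
        (directory / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2)
        )


def build_modular_covariance(truth: GroundTruthSpec, _validate: bool = True) -> np.ndarray:
    """Channel covariance implied by the planted structure.

    Same-module pairs get r_within, different-module pairs r_between; every
    pair involving a hub channel is raised to r_within; unit diagonal. The
    matrix must be positive semi-definite — if not, the construction fails
    naming the offending smallest eigenvalue.
    """
    n = truth.n_channels
    part = np.asarray(truth.partition)
    cov = np.full((n, n), truth.r_between, dtype=float)
    same = part[:, None] == part[None, :]
    cov[same] = truth.r_within
    for h in truth.hub_channels:
        cov[h, :] = truth.r_within
        cov[:, h] = truth.r_within
    np.fill_diagonal(cov, 1.0)
    lo = float(np.linalg.eigvalsh(cov)[0])
    if lo < -1e-10:
        raise ValueError(
            f"planted covariance is not positive semi-definite "
            f"(smallest eigenvalue {lo:.3e})"
        )
    return cov


def _nearest_psd_correlation(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and restore the unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, floor, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def ground_truth_network(truth: GroundTruthSpec) -> BinaryNetwork:
    """The planted blueprint network (deterministic from ``truth.seed``).

    Construction: (1) each hub channel links to ``hub_degree`` neighbours
    drawn round-robin across all modules — the connector-hub pattern;
    (2) every module's non-hub members are joined by a ring (guaranteed
    cohesion) plus random chords, with per-module chord budgets
    proportional to module size, leaving room for ``n_bridges`` distributed
    between-module bridge edges; (3) random within-module edges are
    trimmed (never below within-degree 2) or random between-module edges
    added until the edge count equals
    round(blueprint_sparsity × N(N−1)/2). The result is a connected,
    modular, hub-bridged small-world graph.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x6E657477]))
    n = truth.n_channels
    part = np.asarray(truth.partition)
    modules = list(np.unique(part))
    hubs = list(truth.hub_channels)
    hub_set = set(hubs)
    a = np.zeros((n, n), dtype=np.int8)

    for h in hubs:
        pools = {
            m: list(rng.permutation([x for x in np.flatnonzero(part == m) if x not in hub_set]))
            for m in modules
        }
        order = []
        while any(pools.values()):
            for m in modules:
                if pools[m]:
                    order.append(pools[m].pop())
        for x in order[: truth.hub_degree]:
            a[h, x] = a[x, h] = 1

    K_target = int(round(truth.blueprint_sparsity * n * (n - 1) / 2))
    budget = K_target - int(a.sum()) // 2 - truth.n_bridges
    eff = {m: sum(1 for x in np.flatnonzero(part == m) if x not in hub_set) for m in modules}
    tot = sum(eff.values())
    for m in modules:
        nodes = np.asarray([x for x in np.flatnonzero(part == m) if x not in hub_set])
        nodes = rng.permutation(nodes)
        s = nodes.size
        if s < 2:
            continue
        tgt = int(round(budget * eff[m] / tot))
        for i in range(s):  # connectivity ring
            j = (i + 1) % s
            a[nodes[i], nodes[j]] = a[nodes[j], nodes[i]] = 1
        pairs = [
            (i, j) for i in range(s) for j in range(i + 1, s) if not a[nodes[i], nodes[j]]
        ]
        rng.shuffle(pairs)
        for i, j in pairs[: max(tgt - s, 0)]:
            a[nodes[i], nodes[j]] = a[nodes[j], nodes[i]] = 1

    iu = np.triu_indices(n, k=1)
    K = int(a.sum()) // 2
    within_pairs = [
        (int(i), int(j))
        for i, j in zip(*iu)
        if part[i] == part[j] and a[i, j] and i not in hub_set and j not in hub_set
    ]
    rng.shuffle(within_pairs)
    while K > K_target and within_pairs:
        i, j = within_pairs.pop()
        same_i = part == part[i]
        same_j = part == part[j]
        if a[i][same_i].sum() > 2 and a[j][same_j].sum() > 2 and a[i, j]:
            a[i, j] = a[j, i] = 0
            K -= 1
    between_pairs = [
        (int(i), int(j))
        for i, j in zip(*iu)
        if part[i] != part[j] and not a[i, j] and i not in hub_set and j not in hub_set
    ]
    rng.shuffle(between_pairs)
    while K < K_target and between_pairs:
        i, j = between_pairs.pop()
        a[i, j] = a[j, i] = 1
        K += 1
    return BinaryNetwork(
        adjacency=a, sparsity=truth.blueprint_sparsity, threshold=None,
        channel_ids=[f"ch{i+1}" for i in range(n)],
    )


def ground_truth_matrix(truth: GroundTruthSpec, _check: bool = False) -> np.ndarray:
    """The cohort-level target correlation matrix.

    Blueprint pairs draw strengths from N(r_within, sd_edge²), all other
    pairs from the background tail N(r_between, sd_background²); the
    result is symmetrised, clipped and projected to the nearest
    unit-diagonal PSD correlation matrix. The projection mainly softens
    the (deliberately extreme) hub rows; with ``_check`` its distortion is
    verified (max entry shift ≤ 0.35) as a guard against unrealisable
    parameter combinations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x6D617472]))
    n = truth.n_channels
    bp = ground_truth_network(truth).adjacency.astype(bool)
    part = np.asarray(truth.partition)
    same = part[:, None] == part[None, :]
    strength = rng.normal(0.0, truth.node_strength_sd, size=n)
    background = truth.r_between + strength[:, None] + strength[None, :]
    background = background + truth.within_background_boost * same
    background = np.clip(background, 0.0, 0.9)
    mean = np.where(bp, truth.r_within, background)
    sd = np.where(bp, truth.sd_edge, truth.sd_background)
    for h in truth.hub_channels:
        mean[h, bp[h]] = truth.r_hub
        mean[bp[h], h] = truth.r_hub
    noise = rng.standard_normal((n, n))
    noise = (noise + noise.T) / np.sqrt(2.0)
    raw = np.clip(mean + sd * noise, -0.95, 0.95)
    raw = (raw + raw.T) / 2.0
    np.fill_diagonal(raw, 1.0)
    out = _nearest_psd_correlation(raw)
    if _check:
        shift = float(np.abs(out - raw).max())
        if shift > 0.35:
            raise ValueError(
                f"planted structure is not realisable as a correlation matrix: "
                f"PSD projection shifts a pair target by {shift:.3f} (> 0.15)"
            )
    return out


def _band_limited_noise(
    rng: np.random.Generator, shape: tuple[int, int], fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to ``band`` via FFT masking.

    A common normalisation across channels preserves the cross-channel
    correlation structure exactly (per-channel rescaling would not)."""
    n_ch, n_s = shape
    white = rng.standard_normal((n_ch, n_s))
    f = np.fft.rfftfreq(n_s, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    spec = np.fft.rfft(white, axis=-1)
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n=n_s, axis=-1)
    scale = x.std()
    return x / scale if scale > 0 else x


def _drift(rng: np.random.Generator, n_ch: int, t: np.ndarray) -> np.ndarray:
    """Slow drift: three sinusoids below 0.005 Hz with random phase/weight."""
    freqs = np.array([0.001, 0.002, 0.004])
    out = np.zeros((n_ch, t.size))
    for f0 in freqs:
        amp = rng.uniform(0.3, 1.0, size=(n_ch, 1))
        phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        out += amp * np.sin(2 * np.pi * f0 * t[None, :] + phase)
    s = out.std()
    return out / s if s > 0 else out


def _tone(rng: np.random.Generator, n_ch: int, t: np.ndarray, f0: float) -> np.ndarray:
    """Per-channel sinusoid at ~f0 with random phase and ±2% frequency
    jitter (physiological rhythms are not phase-locked across channels)."""
    f = f0 * (1 + rng.uniform(-0.02, 0.02, size=(n_ch, 1)))
    phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
    x = np.sin(2 * np.pi * f * t[None, :] + phase)
    return x / np.sqrt(0.5)  # unit variance


def _spikes(
    rng: np.random.Generator, n_ch: int, n_s: int, fs: float, rate_per_min: float
) -> np.ndarray:
    """Motion spikes: per-channel Poisson events with 1-s exponential decay."""
    out = np.zeros((n_ch, n_s))
    lam = rate_per_min * (n_s / fs) / 60.0
    decay = np.exp(-np.arange(int(2 * fs)) / fs)
    for c in range(n_ch):
        for _ in range(rng.poisson(lam)):
            i = rng.integers(0, n_s)
            sgn = rng.choice([-1.0, 1.0])
            seg = decay[: n_s - i]
            out[c, i : i + seg.size] += sgn * seg
    return out


def subject_covariance(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-subject jittered correlation targets, projected back to PSD."""
    cov = ground_truth_matrix(spec.truth)
    if spec.jitter_sd > 0:
        n = cov.shape[0]
        noise = rng.normal(0.0, spec.jitter_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        cov = np.clip(cov + noise, -0.99, 0.99)
        np.fill_diagonal(cov, 1.0)
        cov = _nearest_psd_correlation(cov)
    return cov


def simulate_subject(
    spec: CohortSpec, subject_seed: int, subject_id: str = "sub-01"
) -> RawRecording:
    """One subject's two-wavelength optical-density recording.

    Correlated band-limited oxy-Hb signals are drawn from the (jittered)
    planted covariance; deoxy-Hb is −κ·oxy plus independent band-limited
    noise scaled so that corr(oxy, deoxy) = −κ with equal variances;
    nuisance terms are added in concentration space; the forward modified
    Beer-Lambert model maps the result to optical densities.
    """
    rng = np.random.default_rng(subject_seed)
    n_ch, n_s = spec.truth.n_channels, spec.n_samples
    t = np.arange(n_s) / spec.fs
    ids = [f"ch{i+1}" for i in range(n_ch)]

    cov = subject_covariance(spec, rng)
    base = _band_limited_noise(rng, (n_ch, n_s), spec.fs, spec.signal_band)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_ch))
    oxy = spec.hemo_amp * (chol @ base)

    eta = _band_limited_noise(rng, (n_ch, n_s), spec.fs, spec.signal_band)
    deoxy = -spec.kappa * oxy + np.sqrt(1 - spec.kappa**2) * spec.hemo_amp * eta

    nz = spec.noise
    for x in (oxy, deoxy):
        if nz.drift_amp > 0:
            x += nz.drift_amp * spec.hemo_amp * _drift(rng, n_ch, t)
        if nz.nuisance_amp > 0:
            x += nz.nuisance_amp * spec.hemo_amp * _tone(rng, n_ch, t, nz.cardiac_hz)
            x += nz.nuisance_amp * spec.hemo_amp * _tone(rng, n_ch, t, nz.resp_hz)
        if nz.spike_rate > 0:
            x += nz.spike_amp * spec.hemo_amp * _spikes(rng, n_ch, n_s, spec.fs, nz.spike_rate)

    od = beer_lambert_forward(oxy, deoxy, BeerLambertSpec())
    return RawRecording(od=od, fs=spec.fs, channel_ids=ids, subject_id=subject_id)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """All subjects of a cohort, with per-subject seeds spawned from the
    cohort seed."""
    ss = np.random.SeedSequence(spec.truth.seed)
    seeds = [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(spec.n_subjects)]
    recs = [
        simulate_subject(spec, seed, subject_id=f"sub-{i+1:02d}")
        for i, seed in enumerate(seeds)
    ]
    return Cohort(spec=spec, recordings=recs, subject_seeds=seeds)


def toy_graph(name: str, n: int = 0, **kwargs) -> BinaryNetwork:
    """Small graphs with analytically known metrics, as metric fixtures.

    Families: ``complete``, ``ring``, ``star`` (center is node 0), ``path``,
    ``two_cliques`` (two disjoint K_{n/2}), ``erdos_renyi`` (keywords ``p``,
    ``seed``), ``planted_partition`` (keywords ``n_modules``, ``module_size``,
    ``p_in``, ``p_out``, ``seed``).
    """
    if name == "complete":
        g = nx.complete_graph(n)
    elif name == "ring":
        g = nx.cycle_graph(n)
    elif name == "star":
        g = nx.star_graph(n - 1)
    elif name == "path":
        g = nx.path_graph(n)
    elif name == "two_cliques":
        if n % 2:
            raise ValueError("two_cliques needs an even node count")
        g = nx.disjoint_union(nx.complete_graph(n // 2), nx.complete_graph(n // 2))
    elif name == "erdos_renyi":
        g = nx.gnp_random_graph(n, kwargs["p"], seed=kwargs.get("seed", 0))
    elif name == "planted_partition":
        g = nx.planted_partition_graph(
            kwargs.get("n_modules", 4),
            kwargs.get("module_size", 8),
            kwargs.get("p_in", 0.9),
            kwargs.get("p_out", 0.05),
            seed=kwargs.get("seed", 0),
        )
    else:
        raise ValueError(f"unknown toy graph family {name!r}")
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes()), dtype=np.int8)
    m = a.shape[0] * (a.shape[0] - 1) // 2
    k = int(a.sum()) // 2
    return BinaryNetwork(adjacency=a, sparsity=k / m if m else 0.0, threshold=None)
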