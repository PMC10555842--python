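"""Synthetic zonated-lobule generator.

Generates everything the downstream pipeline consumes — cell geometry,
ground-truth zonation profiles, protein matrices, fragment-level
two-channel reports and 4-channel image patches — with the statistical
structure of zonated liver tissue:

* hockey-stick and linear expression profiles along the PV->CV axis;
* abundance- and area-dependent missingness (logistic detection), so
  the per-cell protein count grows with log shape area and completeness
  grows with protein intensity;
* histone intensities coupled linearly to the nuclear fraction of the
  cell slice (a slice can miss the nucleus entirely);
* portal marker channel (E-cadherin, 568 nm) decreasing and central
  marker (Glul, 647 nm) increasing along the axis.

All operations are deterministic given a seed.  Ground truth is kept in
a separate structure (and written to separate files) so consumers cannot
accidentally train on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulatorConfig
from .imaging import landmark_distances
from .zonation import relative_distance

__all__ = [
    "LobuleGeometry",
    "ZonationProfile",
    "LobuleTruth",
    "profile_value",
    "simulate_lobule",
    "simulate_proteome",
    "simulate_report",
    "simulate_images",
]

PROFILE_KINDS = ("hockey_portal", "hockey_central", "linear_up", "linear_down", "flat")


@dataclass(frozen=True)
class LobuleGeometry:
    """Vein landmarks bounding the lobular axis, in um."""

    pv_landmarks: tuple[tuple[float, float], ...]
    cv_landmarks: tuple[tuple[float, float], ...]
    field_size: tuple[float, float]

    def __post_init__(self):
        if not self.pv_landmarks or not self.cv_landmarks:
            raise ValueError("need at least one PV and one CV landmark")
        w, h = self.field_size
        for x, y in (*self.pv_landmarks, *self.cv_landmarks):
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError("landmarks must lie inside the field")


@dataclass(frozen=True)
class ZonationProfile:
    """Expected log2 intensity as a function of relative distance r."""

    protein_id: str
    shape_kind: str
    baseline: float
    amplitude: float = 0.0
    breakpoint: float = 0.0  # r0, for hockey profiles
    gamma: float = 1.0

    def __post_init__(self):
        if self.shape_kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.shape_kind!r}")
        if self.shape_kind == "flat" and self.amplitude != 0.0:
            raise ValueError("flat profiles must have amplitude 0")
        if self.shape_kind.startswith("hockey") and not (0 <= self.breakpoint < 1):
            raise ValueError("hockey breakpoint must lie in [0, 1)")


@dataclass
class LobuleTruth:
    """Ground truth for one simulated section."""

    geometry: LobuleGeometry
    profiles: list[ZonationProfile]
    cells: pd.DataFrame  # cell_id, x, y, area_um2, d_pv, d_cv, r_true, nuclear_fraction, class_true, run, channel
    seed: int
    histone_ids: list[str] = field(default_factory=list)
    ratios: pd.DataFrame | None = None  # true precursor ratios, filled by simulate_report


def profile_value(profile: ZonationProfile, r):
    """Evaluate a zonation profile at relative distance r in [0, 1].

    flat: baseline; linear_up: baseline + A*r; linear_down: baseline +
    A*(1-r); hockey_central: baseline + A*max(0, (r-r0)/(1-r0))**gamma;
    hockey_portal is the mirror image (r replaced by 1-r).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("relative distance must lie in [0, 1]")
    kind = profile.shape_kind
    if kind == "flat":
        out = np.full_like(r, profile.baseline)
    elif kind == "linear_up":
        out = profile.baseline + profile.amplitude * r
    elif kind == "linear_down":
        out = profile.baseline + profile.amplitude * (1.0 - r)
    else:
        rr = 1.0 - r if kind == "hockey_portal" else r
        rise = np.maximum(0.0, (rr - profile.breakpoint) / (1.0 - profile.breakpoint))
        out = profile.baseline + profile.amplitude * rise**profile.gamma
    return out if out.ndim else float(out)


def _make_profiles(config: SimulatorConfig, rng: np.random.Generator) -> tuple[list[ZonationProfile], list[str]]:
    n = config.n_proteins
    n_zonated = int(round(config.zonated_fraction * n))
    kinds = np.array(["flat"] * n, dtype=object)
    zon_kinds = ["hockey_portal", "hockey_central", "linear_up", "linear_down"]
    kinds[:n_zonated] = [zon_kinds[i % 4] for i in range(n_zonated)]
    rng.shuffle(kinds)

    profiles = []
    histone_ids = []
    n_hist = min(config.n_histones, int((kinds == "flat").sum()))
    flat_idx = iter(np.flatnonzero(kinds == "flat"))
    histone_positions = {next(flat_idx) for _ in range(n_hist)}
    for i, kind in enumerate(kinds):
        pid = f"P{i + 1:04d}"
        if i in histone_positions:
            pid = f"HIST{len(histone_ids) + 1}"
            histone_ids.append(pid)
            profiles.append(ZonationProfile(pid, "flat", baseline=config.histone_baseline))
            continue
        baseline = float(rng.normal(config.baseline_mean, config.baseline_sd))
        if kind == "flat":
            profiles.append(ZonationProfile(pid, "flat", baseline=baseline))
        else:
            amp = float(rng.uniform(config.amplitude_low, config.amplitude_high))
            r0 = float(rng.uniform(config.breakpoint_low, config.breakpoint_high))
            gamma = float(rng.uniform(config.gamma_low, config.gamma_high))
            profiles.append(ZonationProfile(pid, kind, baseline, amp, r0, gamma))
    return profiles, histone_ids


def simulate_lobule(
    n_cells: int,
    config: SimulatorConfig | None = None,
    seed: int = 0,
    profiles: list[ZonationProfile] | None = None,
    histone_ids: list[str] | None = None,
) -> LobuleTruth:
    """Simulate cell geometry and ground truth for one section.

    Cells are placed along the axis between the nearest PV/CV landmark
    pair (uniform in axis position, with transverse jitter), areas are
    lognormal with median 600 um2 truncated at the 135-1350 um2
    segmentation gates, and the nuclear fraction has a point mass at 0
    (anucleate slices).  ``r_true`` is recomputed from the centroid and
    the landmarks with the same formula the spatial analysis uses.
    Passing ``profiles`` reuses an existing protein panel so that two
    sections share ground truth (e.g. train/held-out splits).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    config = config or SimulatorConfig()
    rng = np.random.default_rng(seed)
    geometry = LobuleGeometry(
        tuple(tuple(p) for p in config.pv_landmarks),
        tuple(tuple(p) for p in config.cv_landmarks),
        tuple(config.field_size),
    )
    if profiles is None:
        profiles, histone_ids = _make_profiles(config, rng)
    elif histone_ids is None:
        histone_ids = [p.protein_id for p in profiles if p.protein_id.startswith("HIST")]

    pv = np.asarray(geometry.pv_landmarks, dtype=float)
    cv = np.asarray(geometry.cv_landmarks, dtype=float)
    if config.placement == "axis":
        # uniform position along a randomly chosen PV->CV segment
        t = rng.uniform(0.0, 1.0, n_cells)
        pv_pick = pv[rng.integers(0, len(pv), n_cells)]
        cv_pick = cv[rng.integers(0, len(cv), n_cells)]
        axis = cv_pick - pv_pick
        pos = pv_pick + t[:, None] * axis
        if config.transverse_jitter_um > 0:
            normal = np.stack([-axis[:, 1], axis[:, 0]], axis=1)
            norm_len = np.linalg.norm(normal, axis=1, keepdims=True)
            normal = normal / np.where(norm_len > 0, norm_len, 1.0)
            pos = pos + normal * rng.normal(0.0, config.transverse_jitter_um, n_cells)[:, None]
        pos[:, 0] = np.clip(pos[:, 0], 0, geometry.field_size[0])
        pos[:, 1] = np.clip(pos[:, 1], 0, geometry.field_size[1])
    elif config.placement == "uniform":
        pos = rng.uniform((0, 0), geometry.field_size, size=(n_cells, 2))
    else:
        raise ValueError(f"unknown placement {config.placement!r}")

    d_pv = np.empty(n_cells)
    d_cv = np.empty(n_cells)
    for i in range(n_cells):
        d_pv[i], d_cv[i] = landmark_distances(pos[i], pv, cv)
    r_true = relative_distance(d_pv, d_cv)

    # lognormal areas truncated at the segmentation gates (resampled)
    mu = np.log(config.area_log_median_um2)
    areas = np.exp(rng.normal(mu, config.area_log_sd, n_cells))
    for _ in range(100):
        bad = (areas < config.area_min_um2) | (areas > config.area_max_um2)
        if not bad.any():
            break
        areas[bad] = np.exp(rng.normal(mu, config.area_log_sd, int(bad.sum())))
    areas = np.clip(areas, config.area_min_um2, config.area_max_um2)

    nuclear = rng.beta(2.0, 2.0, n_cells)
    nuclear[rng.uniform(size=n_cells) < config.anucleate_fraction] = 0.0

    K = config.n_classes
    class_true = np.minimum((r_true * K).astype(int) + 1, K)

    # two single-shape channels per run (dimethyl Δ4 / Δ8)
    runs = [f"R{i // 2 + 1:04d}" for i in range(n_cells)]
    channels = [4 if i % 2 == 0 else 8 for i in range(n_cells)]

    cells = pd.DataFrame({
        "cell_id": [f"C{i + 1:04d}" for i in range(n_cells)],
        "x": pos[:, 0],
        "y": pos[:, 1],
        "area_um2": areas,
        "d_pv": d_pv,
        "d_cv": d_cv,
        "r_true": r_true,
        "nuclear_fraction": nuclear,
        "class_true": class_true,
        "run": runs,
        "channel": channels,
    }).set_index("cell_id")

    return LobuleTruth(geometry=geometry, profiles=profiles, cells=cells,
                       seed=seed, histone_ids=histone_ids)


def simulate_proteome(
    truth: LobuleTruth,
    config: SimulatorConfig | None = None,
    noise_sd: float | None = None,
    missingness: bool | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ground-truth protein x cell log2 intensity matrix with missingness.

    Observed value = profile(r_true) + area_coef*log2(area/median area)
    + histone_coef*nuclear_fraction (histones only) + N(0, noise_sd).
    Detection is Bernoulli with logistic probability in the expected
    log2 intensity (which includes the area term), so protein counts
    grow with log area and completeness with abundance.
    """
    config = config or SimulatorConfig()
    noise_sd = config.noise_sd if noise_sd is None else noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    missingness = config.missingness if missingness is None else missingness
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)

    cells = truth.cells
    r = cells["r_true"].to_numpy()
    area_term = config.area_coef * np.log2(cells["area_um2"].to_numpy() / config.area_log_median_um2)
    nuclear = cells["nuclear_fraction"].to_numpy()

    n_prot, n_cell = len(truth.profiles), len(cells)
    X = np.empty((n_prot, n_cell))
    expected = np.empty_like(X)
    for i, prof in enumerate(truth.profiles):
        mu = profile_value(prof, r) + area_term
        if prof.protein_id in truth.histone_ids:
            mu = mu + config.histone_coef * nuclear
        expected[i] = mu
    X = expected + rng.normal(0.0, noise_sd, size=X.shape) if noise_sd > 0 else expected.copy()

    if missingness:
        p_detect = 1.0 / (1.0 + np.exp(-(expected - config.detect_midpoint) / config.detect_scale))
        # abundant signal is always found (match-between-runs certainty)
        p_detect[expected >= config.detect_midpoint + config.detect_saturation] = 1.0
        X[rng.uniform(size=X.shape) >= p_detect] = np.nan

    return pd.DataFrame(X, index=[p.protein_id for p in truth.profiles], columns=cells.index)


def simulate_report(
    matrix: pd.DataFrame,
    truth: LobuleTruth,
    config: SimulatorConfig | None = None,
    frag_per_precursor: int | None = None,
    ratio_noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fragment-level two-channel precursor report for a protein matrix.

    Each detected protein x cell entry is spread over a fixed number of
    precursors with per-protein share weights.  Reference (Δ0) rows get
    per-run intensities around a per-precursor reference level; target
    rows are reference fragments times the true target/reference ratio
    times multiplicative noise.  The true ratio is defined against the
    median realised reference level over runs — exactly the statistic
    the quantification recomputes — and is recorded in
    ``truth.ratios``.  Q-value columns are drawn so a configured
    fraction of rows fails each threshold, independently per row.
    """
    config = config or SimulatorConfig()
    F = config.frag_per_precursor if frag_per_precursor is None else frag_per_precursor
    if F < 1:
        raise ValueError("frag_per_precursor must be >= 1")
    ratio_noise_sd = config.ratio_noise_sd if ratio_noise_sd is None else ratio_noise_sd
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)

    cells = truth.cells
    runs = sorted(cells["run"].unique())
    proteins = list(matrix.index)
    nP = config.precursors_per_protein

    # fixed per-protein precursor shares and per-precursor fragment shares
    prec_share = rng.dirichlet(np.full(nP, 5.0), size=len(proteins))
    frag_share = rng.dirichlet(np.full(F, 5.0), size=(len(proteins), nP))

    # per-run reference levels; the reference channel is bulk proteome at higher load
    base_level = {}
    ref_levels = {}
    for gi, prof in enumerate(truth.profiles):
        if prof.protein_id not in matrix.index:
            continue
        B = 2.0 ** (prof.baseline + config.ref_offset_log2)
        for j in range(nP):
            b = B * prec_share[gi, j]
            base_level[(prof.protein_id, j)] = b
            noise = np.exp(rng.normal(0.0, config.ref_run_noise_sd, len(runs)))
            ref_levels[(prof.protein_id, j)] = dict(zip(runs, b * noise))

    med_ref = {
        key: float(np.median(list(levels.values())))
        for key, levels in ref_levels.items()
    }

    prot_index = {p.protein_id: gi for gi, p in enumerate(truth.profiles)}
    rows = []
    ratio_records = []

    def _qvals(n):
        lib = np.where(rng.uniform(size=n) < config.q_fail_lib,
                       rng.uniform(0.01, 0.5, n), rng.uniform(0.0, 0.0099, n))
        qv = np.where(rng.uniform(size=n) < config.q_fail_q,
                      rng.uniform(0.01, 0.5, n), rng.uniform(0.0, 0.0099, n))
        ch = np.where(rng.uniform(size=n) < config.q_fail_channel,
                      rng.uniform(0.15, 1.0, n), rng.uniform(0.0, 0.1499, n))
        return lib, qv, ch

    ms1_share = config.ms1_share
    for run in runs:
        run_cells = cells[cells["run"] == run]
        for gid in proteins:
            gi = prot_index[gid]
            detected = {
                cell_id: matrix.at[gid, cell_id]
                for cell_id in run_cells.index
                if np.isfinite(matrix.at[gid, cell_id])
            }
            if not detected:
                continue
            for j in range(nP):
                prec_id = f"{gid}_pre{j + 1}"
                ref_total = ref_levels[(gid, j)][run]
                ref_frags = ref_total * (1.0 - ms1_share) * frag_share[gi, j]
                ref_ms1 = ref_total * ms1_share
                rows.append((run, gid, prec_id, 0, ref_ms1, ref_frags))
                for cell_id, log2_val in detected.items():
                    channel = int(cells.at[cell_id, "channel"])
                    target_total = prec_share[gi, j] * 2.0**log2_val
                    rho = target_total / med_ref[(gid, j)]
                    mult = (np.exp(rng.normal(0.0, ratio_noise_sd, F + 1))
                            if ratio_noise_sd > 0 else np.ones(F + 1))
                    t_frags = ref_frags * rho * mult[:F]
                    t_ms1 = ref_ms1 * rho * mult[F]
                    rows.append((run, gid, prec_id, channel, t_ms1, t_frags))
                    ratio_records.append({
                        "cell_id": cell_id, "run": run, "channel": channel,
                        "protein_group": gid, "precursor_id": prec_id, "ratio": rho,
                    })

    n = len(rows)
    lib, qv, ch = _qvals(n)
    report = pd.DataFrame({
        "Run": [r[0] for r in rows],
        "Protein.Group": [r[1] for r in rows],
        "Precursor.Id": [r[2] for r in rows],
        "Channel": [r[3] for r in rows],
        "Ms1.Area": [r[4] for r in rows],
        "Fragment.Quant.Raw": [";".join(f"{x:.17g}" for x in r[5]) for r in rows],
        "Lib.PG.Q.Value": lib,
        "Q.Value": qv,
        "Channel.Q.Value": ch,
    })
    truth.ratios = pd.DataFrame.from_records(ratio_records)
    return report


def simulate_images(
    truth: LobuleTruth,
    config: SimulatorConfig | None = None,
    patch_size: int | None = None,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-cell 4-channel image patches keyed by cell id.

    Channel order follows the canonical stain order (425 phalloidin,
    488 WGA, 568 E-cadherin, 647 Glul).  The 568 mean decreases and the
    647 mean increases with relative distance; 425/488 are weakly
    informative.  Pixel noise is additive Gaussian truncated at 0.
    """
    config = config or SimulatorConfig()
    ps = config.patch_size if patch_size is None else patch_size
    if ps < 4:
        raise ValueError("patch_size must be >= 4")
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)

    patches = {}
    for cell_id, cell in truth.cells.iterrows():
        r = cell["r_true"]
        levels = np.array([
            config.ch425_level,
            config.ch488_base + config.ch488_nuclear_amp * cell["nuclear_fraction"],
            config.ch568_base + config.ch568_amp * (1.0 - r),
            config.ch647_base + config.ch647_amp * r,
        ])
        patch = levels[:, None, None] + rng.normal(0.0, config.pixel_noise_sd, (4, ps, ps))
        patches[cell_id] = np.maximum(patch, 0.0)
    return patches
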