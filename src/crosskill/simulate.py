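"""Synthetic screen, dose-response, combination, xenograft and survival data.

Every generator is a pure function of its parameters and an integer seed, and
emits the plain tabular formats the rest of the package consumes.  Ground
truth (per-compound killing, planted synergy, planted hazards) is returned
alongside the data so that downstream stages can be validated end to end.

The screen generator emulates a CellTiter-Glo style viability screen: 384- or
96-well plates, compounds stamped in replicate at a single dose, vehicle
(DMSO) control wells in fixed columns, and luminescence proportional to
surviving cells.  Percent killing for a well with true effect k is encoded as
``lum = L_plate * (1 - k/100) + noise`` so that plate normalization recovers
k exactly in the noise-free limit.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenTruth",
    "generate_compound_library",
    "generate_screen",
    "generate_dose_response",
    "generate_combination_grid",
    "generate_tumor_study",
    "generate_survival_cohort",
    "shared_effect_sd",
    "four_pl",
    "PLATE_DIMS",
]

#: plate geometry: wells -> (rows, columns)
PLATE_DIMS = {96: (8, 12), 384: (16, 24)}

DEFAULT_CONTROL_LEVEL = 1.0e6  # RLU; plate control level drawn log-normally around this
DEFAULT_SPECIES_SD = 6.0       # pp, per-(species, compound) offset
DEFAULT_LINE_SD = 4.0          # pp, per-(line, compound) offset
DEFAULT_NOISE_SD = 8.0         # pp, well-level residual


def _rng(seed, *tags):
    """Deterministic generator derived from an integer seed plus string/int tags."""
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        keys.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


def four_pl(c, top, bottom, ic50, hill):
    """Four-parameter logistic response: bottom + (top-bottom)/(1+(c/ic50)^hill)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def shared_effect_sd(target_r2, *, species_sd, line_sd=0.0, noise_sd=0.0,
                     n_replicates=3, n_lines_a=1, n_lines_b=1):
    """Standard deviation of the shared per-compound effect that plants a given R².

    The screen decomposes a compound's true killing into a shared component
    (same in every line), a species offset and a line offset, plus well noise
    averaged over replicates.  The squared Pearson correlation between the two
    species' per-compound killing profiles (species means when a species has
    several lines) is then

        R² = [ s² / sqrt((s² + v_a)(s² + v_b)) ]²

    with s² the shared variance and v the species-specific variance seen by
    each profile.  Given a target R² this solves for s.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    r = float(np.sqrt(target_r2))
    v_a = species_sd**2 + (line_sd**2 + noise_sd**2 / n_replicates) / n_lines_a
    v_b = species_sd**2 + (line_sd**2 + noise_sd**2 / n_replicates) / n_lines_b
    v = float(np.sqrt(v_a * v_b))  # geometric mean; exact when v_a == v_b
    return float(np.sqrt(r * v / (1.0 - r)))


@dataclass
class ScreenTruth:
    """Planted ground truth behind a synthetic screen.

    ``compound_effects`` is the shared per-compound mean percent killing;
    species and line offsets (additive, percentage points) are either given
    explicitly or drawn deterministically from ``species_sd``/``line_sd`` and
    the seed the first time a species/line name is seen.  Compounds in
    ``sensitive_compounds`` (planted multi-line-sensitive driver drugs) take
    no offsets, so their true killing stays above the hit threshold in every
    line.  When ``inactive_ceiling`` is set (as :func:`generate_compound_library`
    does) every other compound is capped at that killing so the planted
    separation around the threshold is unambiguous; manually built truths
    default to no ceiling.
    """

    compound_effects: pd.Series
    noise_sd: float = DEFAULT_NOISE_SD
    species_sd: float = DEFAULT_SPECIES_SD
    line_sd: float = DEFAULT_LINE_SD
    species_mean_shift: dict = field(default_factory=dict)
    species_offsets: pd.DataFrame | None = None
    line_offsets: pd.DataFrame | None = None
    driver_targets: tuple = ()
    sensitive_compounds: frozenset = frozenset()
    inactive_ceiling: float | None = None
    seed: int = 0

    def __post_init__(self):
        eff = np.asarray(self.compound_effects, dtype=float)
        if not np.all(np.isfinite(eff)):
            raise ValueError("compound_effects must be finite")
        if self.compound_effects.index.has_duplicates:
            raise ValueError("duplicate compound ids in truth")

    @property
    def compounds(self):
        return list(self.compound_effects.index)

    def _offset(self, kind, name, sd):
        explicit = self.species_offsets if kind == "species" else self.line_offsets
        if explicit is not None and name in explicit.index:
            return explicit.loc[name].reindex(self.compound_effects.index).to_numpy(float)
        shift = self.species_mean_shift.get(name, 0.0) if kind == "species" else 0.0
        rng = _rng(self.seed, "offset", kind, name)
        return shift + rng.normal(0.0, sd, size=len(self.compound_effects))

    def true_killing(self, cell_lines):
        """True percent killing per (cell line, compound).

        Parameters
        ----------
        cell_lines : list of (name, species) pairs.

        Returns
        -------
        DataFrame, rows = cell lines, columns = compounds.
        """
        base = self.compound_effects.to_numpy(float)
        sens = self.compound_effects.index.isin(self.sensitive_compounds)
        rows = {}
        for name, species in cell_lines:
            k = base + self._offset("species", species, self.species_sd) \
                     + self._offset("line", name, self.line_sd)
            k = np.where(sens, base, k)  # driver drugs: planted effect only
            if self.inactive_ceiling is not None:
                k = np.where(sens, k, np.minimum(k, self.inactive_ceiling))
            rows[name] = k
        return pd.DataFrame(rows, index=self.compound_effects.index).T


def generate_compound_library(n_targets, drugs_per_target=(6, 14), driver_spec=(),
                              seed=0, *, n_compounds=None,
                              sensitive_range=(65.0, 95.0),
                              resistant_range=(5.0, 40.0),
                              background_range=(0.0, 40.0),
                              noise_sd=DEFAULT_NOISE_SD,
                              species_sd=DEFAULT_SPECIES_SD,
                              line_sd=DEFAULT_LINE_SD,
                              inactive_ceiling=48.0):
    """Build an annotated compound library with planted driver targets.

    ``driver_spec`` is a list of ``(target, n_drugs, n_sensitive)``: each
    driver target gets ``n_drugs`` compounds of which ``n_sensitive`` are
    planted sensitive (true killing above 50% in every line) and the rest
    resistant (below 50% everywhere).  Background compounds are spread over
    the remaining targets with true killing held below 50% in every line
    (the ``inactive_ceiling`` caps offset excursions), so hits and passing
    targets in the emitted screen are attributable to the planted drivers.

    Returns ``(annotation, truth)`` where ``annotation`` is a DataFrame with
    columns compound_id, name, targets (frozenset), pathway, and ``truth`` is
    a :class:`ScreenTruth`.
    """
    driver_spec = list(driver_spec)
    names = [d[0] for d in driver_spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate target names in driver_spec")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if len(driver_spec) > n_targets:
        raise ValueError("more driver targets than n_targets")
    for target, n_drugs, n_sens in driver_spec:
        if n_sens > n_drugs:
            raise ValueError(f"driver {target!r}: n_sensitive > n_drugs")

    rng = _rng(seed, "library")
    n_driver_drugs = sum(d[1] for d in driver_spec)
    n_background_targets = n_targets - len(driver_spec)

    # background target sizes
    if n_compounds is not None:
        n_background = n_compounds - n_driver_drugs
        if n_background < n_background_targets:
            raise ValueError("n_compounds too small for the requested targets")
        sizes = np.full(n_background_targets, n_background // n_background_targets)
        sizes[: n_background % n_background_targets] += 1
    else:
        lo, hi = (drugs_per_target, drugs_per_target) if np.isscalar(drugs_per_target) \
            else drugs_per_target
        sizes = rng.integers(int(lo), int(hi) + 1, size=n_background_targets)

    records, effects, sensitive = [], [], []
    idx = 0
    for target, n_drugs, n_sens in driver_spec:
        for k in range(n_drugs):
            cid = f"C{idx:04d}"
            is_sens = k < n_sens
            lo, hi = sensitive_range if is_sens else resistant_range
            effects.append(rng.uniform(lo, hi))
            if is_sens:
                sensitive.append(cid)
            records.append((cid, f"{target}_drug_{k + 1:02d}", frozenset({target}),
                            f"{target} pathway"))
            idx += 1
    for t, size in enumerate(sizes):
        target = f"TGT_{t + 1:03d}"
        for k in range(size):
            cid = f"C{idx:04d}"
            effects.append(rng.uniform(*background_range))
            records.append((cid, f"{target}_drug_{k + 1:02d}", frozenset({target}),
                            f"{target} pathway"))
            idx += 1

    annotation = pd.DataFrame(records, columns=["compound_id", "name", "targets", "pathway"])
    truth = ScreenTruth(
        compound_effects=pd.Series(effects, index=annotation["compound_id"], name="true_killing"),
        noise_sd=noise_sd, species_sd=species_sd, line_sd=line_sd,
        driver_targets=tuple(names), sensitive_compounds=frozenset(sensitive),
        inactive_ceiling=inactive_ceiling, seed=seed,
    )
    return annotation, truth


def _plate_layout(plate_size, control_wells_per_plate):
    n_rows, n_cols = PLATE_DIMS[plate_size]
    n_control_cols = int(np.ceil(control_wells_per_plate / n_rows))
    if n_control_cols >= n_cols:
        raise ValueError("control wells leave no treated wells on the plate")
    treated_cols = n_cols - n_control_cols
    row_labels = [chr(ord("A") + r) for r in range(n_rows)]
    treated_wells = [f"{row_labels[r]}{c + 1:02d}"
                     for r in range(n_rows) for c in range(treated_cols)]
    reserved = [f"{row_labels[r]}{c + 1:02d}"
                for c in range(treated_cols, n_cols) for r in range(n_rows)]
    control_wells = reserved[:control_wells_per_plate]
    blank_wells = reserved[control_wells_per_plate:]
    return treated_wells, control_wells, blank_wells


def generate_screen(truth, cell_lines, n_replicates=3, control_wells_per_plate=32,
                    plate_size=384, seed=0, *, control_level_mean=DEFAULT_CONTROL_LEVEL,
                    control_level_cv=0.1, edge_effect=0.0):
    """Emit a well-level luminescence table for one screen.

    Each (cell line, compound) gets exactly ``n_replicates`` treated wells,
    replicates stamped into consecutive wells; vehicle-control wells occupy
    the rightmost plate columns.  Compounds that overflow a plate are
    paginated onto further plates for the same cell line.  Luminescence is
    ``L_plate * (1 - k/100) + N(0, noise_sd/100 * L_plate)`` with the plate
    control level L drawn log-normally around ``control_level_mean``; negative
    values are clipped at zero and flagged.  ``edge_effect`` (fractional
    signal loss on outer-ring wells, default off) can be enabled to stress
    normalization.

    Returns a DataFrame with columns plate_id, well, role, cell_line, species,
    compound_id, replicate, luminescence_rlu, clipped.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if plate_size not in PLATE_DIMS:
        raise ValueError(f"plate_size must be one of {sorted(PLATE_DIMS)}")
    treated_wells, control_wells, blank_wells = _plate_layout(plate_size, control_wells_per_plate)
    per_plate = len(treated_wells)

    killing = truth.true_killing(cell_lines)
    compounds = np.asarray(killing.columns)
    n_comp = len(compounds)
    rng = _rng(seed, "screen")
    sigma = float(np.log1p(control_level_cv))

    n_slots = n_comp * n_replicates
    n_plates = int(np.ceil(n_slots / per_plate))
    # one treated slot per (compound, replicate), replicates consecutive
    comp_idx = np.repeat(np.arange(n_comp), n_replicates)
    rep_idx = np.tile(np.arange(1, n_replicates + 1), n_comp)
    plate_of_slot = np.arange(n_slots) // per_plate
    well_of_slot = np.asarray(treated_wells)[np.arange(n_slots) % per_plate]
    ctrl_wells = np.asarray(control_wells)
    blanks = np.asarray(blank_wells)

    frames = []
    for name, species in cell_lines:
        k_line = killing.loc[name].to_numpy(float)
        levels = control_level_mean * np.exp(rng.normal(0.0, sigma, size=n_plates))
        plate_ids = np.array([f"{name}_P{p + 1:02d}" for p in range(n_plates)])

        t_level = levels[plate_of_slot]
        mu_t = t_level * (1.0 - k_line[comp_idx] / 100.0)
        mu_c = np.repeat(levels, len(ctrl_wells))
        mu_b = np.zeros(n_plates * len(blanks))
        plate = pd.DataFrame({
            "plate_id": np.concatenate([plate_ids[plate_of_slot],
                                        np.repeat(plate_ids, len(ctrl_wells)),
                                        np.repeat(plate_ids, len(blanks))]),
            "well": np.concatenate([well_of_slot, np.tile(ctrl_wells, n_plates),
                                    np.tile(blanks, n_plates)]),
            "role": np.concatenate([np.repeat("treated", n_slots),
                                    np.repeat("vehicle_control", n_plates * len(ctrl_wells)),
                                    np.repeat("blank", n_plates * len(blanks))]),
            "cell_line": name,
            "species": species,
            "compound_id": np.concatenate([compounds[comp_idx],
                                           np.repeat("", n_plates * (len(ctrl_wells)
                                                                     + len(blanks)))]),
            "replicate": np.concatenate([rep_idx,
                                         np.zeros(n_plates * (len(ctrl_wells)
                                                              + len(blanks)), int)]),
        })
        mu = np.concatenate([mu_t, mu_c, mu_b])
        if edge_effect:
            mu = mu * (1.0 - edge_effect * _is_edge(plate["well"].to_numpy(), plate_size))
        level_row = np.concatenate([t_level, mu_c, np.repeat(levels, len(blanks))])
        if truth.noise_sd:
            lum = mu + rng.normal(0.0, 1.0, size=len(mu)) * (truth.noise_sd / 100.0
                                                             * level_row)
        else:
            lum = mu
        clipped = lum < 0
        plate["luminescence_rlu"] = np.where(clipped, 0.0, lum)
        plate["clipped"] = clipped
        frames.append(plate)
    return pd.concat(frames, ignore_index=True)


def _is_edge(wells, plate_size):
    n_rows, n_cols = PLATE_DIMS[plate_size]
    rows = np.array([ord(w[0]) - ord("A") for w in wells])
    cols = np.array([int(w[1:]) - 1 for w in wells])
    return ((rows == 0) | (rows == n_rows - 1) | (cols == 0) | (cols == n_cols - 1)).astype(float)


def generate_dose_response(true_top, true_bottom, true_ic50, true_hill,
                           concentrations, noise_sd=0.0, n_reps=1, seed=0):
    """Dose-viability table from a 4PL curve with additive Gaussian noise.

    Expected viability at concentration c is
    ``bottom + (top - bottom)/(1 + (c/ic50)^hill)`` (percent scale).
    """
    conc = np.asarray(concentrations, dtype=float)
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _rng(seed, "dose")
    c = np.repeat(conc, n_reps)
    mu = four_pl(c, true_top, true_bottom, true_ic50, true_hill)
    v = mu + (rng.normal(0.0, noise_sd, size=len(c)) if noise_sd else 0.0)
    return pd.DataFrame({
        "concentration_uM": c,
        "replicate": np.tile(np.arange(1, n_reps + 1), len(conc)),
        "viability_pct": v,
    })


def generate_combination_grid(effect_a, effect_b, planted_excess=None,
                              noise_sd=0.0, seed=0, doses_a=None, doses_b=None):
    """Checkerboard combination grid with Bliss-planted interaction.

    ``effect_a``/``effect_b`` are single-agent inhibition fractions per dose;
    the observed interior inhibition is
    ``Ea + Eb - Ea*Eb + planted_excess`` plus noise, clipped to [0, 1] (a
    warning is emitted if the noise-free expectation itself needs clipping).
    Returns a DataFrame indexed by dose_a (rows, including 0) and dose_b
    (columns, including 0) of observed inhibition fractions.
    """
    ea = np.asarray(effect_a, dtype=float)
    eb = np.asarray(effect_b, dtype=float)
    if np.any((ea < 0) | (ea > 1)) or np.any((eb < 0) | (eb > 1)):
        raise ValueError("single-agent effects must be fractions in [0, 1]")
    excess = np.zeros((len(ea), len(eb))) if planted_excess is None \
        else np.asarray(planted_excess, dtype=float)
    if excess.shape != (len(ea), len(eb)):
        raise ValueError("planted_excess shape must be (len(effect_a), len(effect_b))")
    da = np.arange(1, len(ea) + 1, dtype=float) if doses_a is None else np.asarray(doses_a, float)
    db = np.arange(1, len(eb) + 1, dtype=float) if doses_b is None else np.asarray(doses_b, float)

    expected = ea[:, None] + eb[None, :] - ea[:, None] * eb[None, :] + excess
    if np.any((expected < 0) | (expected > 1)):
        warnings.warn("planted excess pushes expected inhibition outside [0, 1]; clipped")
        expected = np.clip(expected, 0.0, 1.0)

    full = np.zeros((len(ea) + 1, len(eb) + 1))
    full[1:, 0] = ea
    full[0, 1:] = eb
    full[1:, 1:] = expected
    if noise_sd:
        rng = _rng(seed, "combo")
        noise = rng.normal(0.0, noise_sd, size=full.shape)
        noise[0, 0] = 0.0
        full = np.clip(full + noise, 0.0, 1.0)
    return pd.DataFrame(full, index=np.concatenate([[0.0], da]),
                        columns=np.concatenate([[0.0], db]))


DEFAULT_MEASURE_DAYS = tuple(range(0, 19, 2))  # alternating days, ~3 measurements/week


def generate_tumor_study(groups, v0=100.0, measure_days=DEFAULT_MEASURE_DAYS,
                         noise_sd=0.0, seed=0):
    """Caliper table for a xenograft treatment study.

    Each group is ``(name, n_mice, daily_growth_rate)``; the underlying volume
    follows ``v0 * exp(rate * day)`` with additive Gaussian noise (mm³) on the
    volume, and length/width pairs are emitted so that (L × W²)/2 reproduces
    the noisy volume exactly (aspect ratio L/W drawn in [1, 1.5]).
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    days = np.asarray(measure_days, dtype=float)
    rng = _rng(seed, "tumor")
    rows = []
    for gname, n_mice, rate in groups:
        if n_mice < 1:
            raise ValueError(f"group {gname!r} has zero mice")
        for m in range(n_mice):
            vol = v0 * np.exp(rate * days)
            if noise_sd:
                vol = vol + rng.normal(0.0, noise_sd, size=len(days))
            vol = np.maximum(vol, 1e-3)
            aspect = rng.uniform(1.0, 1.5, size=len(days))
            width = np.cbrt(2.0 * vol / aspect)
            length = aspect * width
            for d, L, W in zip(days, length, width):
                rows.append((f"{gname}_m{m + 1:02d}", gname, d, L, W))
    return pd.DataFrame(rows, columns=["mouse_id", "group", "day", "length_mm", "width_mm"])


def generate_survival_cohort(n, cutoff, hazard_low, hazard_high,
                             censor_rate=0.0, seed=0, expression_range=(0.0, 10.0)):
    """Two-hazard survival cohort keyed on a continuous expression marker.

    Subjects with expression above ``cutoff`` draw exponential event times at
    ``hazard_high``; the rest at ``hazard_low``.  With probability
    ``censor_rate`` a subject is censored at a uniform fraction of its event
    time.
    """
    if n < 4:
        raise ValueError("n must be >= 4 (cutoff scan undefined below that)")
    if hazard_low <= 0 or hazard_high <= 0:
        raise ValueError("hazards must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = _rng(seed, "survival")
    expr = rng.uniform(*expression_range, size=n)
    hazard = np.where(expr > cutoff, hazard_high, hazard_low)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censor_rate
    t = np.where(censored, t_event * rng.uniform(0.05, 1.0, size=n), t_event)
    return pd.DataFrame({
        "subject": [f"S{i + 1:03d}" for i in range(n)],
        "expression": expr,
        "time": t,
        "event": (~censored).astype(int),
    })
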