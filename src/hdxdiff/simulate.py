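"""Forward simulation of peptide-level HDX-MS datasets.

The generator produces uptake tables with the kinetic structure the
downstream analysis assumes: Linderstrøm-Lang EX2 kinetics with per-residue
intrinsic rates attenuated by protection factors, purely base-catalysed pH
dependence (``k(pH) = k_ref * 10**(pH - pH_ref)``), optional irreversible
two-state unfolding to a molten-globule-like state, uniform back exchange,
and homoscedastic Gaussian replicate noise.  Intrinsic rates are relative
quantities supplied by the user or drawn at random; the analysis only ever
consumes rate ratios, so no sequence-context (Bai/Englander) correction is
attempted.

Coordinates are 1-based inclusive.  Uptake is in Da-equivalents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corrections import LabellingCondition
from .io import PeptideRecord

__all__ = [
    "ResidueExchangeModel",
    "Unfolding",
    "ConformationalState",
    "ExperimentDesign",
    "random_protein_sequence",
    "random_exchange_model",
    "uniform_state",
    "generate_peptide_map",
    "ex2_uptake",
    "simulate_dataset",
    "simulate_two_state",
    "CONTROL_EXPOSURE_S",
]

#: Exposure recorded for maximally labelled control rows (24 h).
CONTROL_EXPOSURE_S = 86400.0

_AA = "ACDEFGHIKLMNQRSTVWY"  # proline handled separately


@dataclass(frozen=True)
class ResidueExchangeModel:
    """Per-residue intrinsic exchange rates of an unprotected chain.

    ``k_int_ref`` holds the chemical exchange rate of each backbone amide at
    ``reference_pH`` (1/s).  Prolines and the first residue carry rate
    exactly 0: neither has an exchangeable backbone amide that retains label.
    """

    sequence: str
    k_int_ref: np.ndarray
    reference_pH: float

    def __post_init__(self) -> None:
        k = np.asarray(self.k_int_ref, dtype=float)
        object.__setattr__(self, "k_int_ref", k)
        if len(k) != len(self.sequence):
            raise ValueError("k_int_ref length must equal sequence length")
        if np.any(k < 0):
            raise ValueError("intrinsic rates must be non-negative")
        fixed_zero = [0] + [i for i, aa in enumerate(self.sequence) if aa == "P"]
        if np.any(k[fixed_zero] != 0.0):
            raise ValueError("prolines and the first residue must have rate 0")

    def rates_at(self, pH: float) -> np.ndarray:
        """Intrinsic rates at another pH under pure base catalysis."""
        return self.k_int_ref * 10.0 ** (pH - self.reference_pH)


@dataclass(frozen=True)
class Unfolding:
    """Irreversible two-state conversion folded -> open (molten globule).

    ``k_open`` is the first-order opening rate (1/s); ``log10_pf_open`` the
    per-residue protection profile of the open state (typically near 0,
    i.e. random-coil-like exchange).
    """

    k_open: float
    log10_pf_open: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "log10_pf_open", np.asarray(self.log10_pf_open, dtype=float))
        if self.k_open < 0:
            raise ValueError("k_open must be non-negative")
        if np.any(self.log10_pf_open < 0):
            raise ValueError("protection factors must be >= 1 (log10 >= 0)")


@dataclass(frozen=True)
class ConformationalState:
    """Named per-residue protection-factor profile, optionally unfoldable."""

    name: str
    log10_pf: np.ndarray
    unfolding: Unfolding | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "log10_pf", np.asarray(self.log10_pf, dtype=float))
        if np.any(self.log10_pf < 0):
            raise ValueError("protection factors must be >= 1 (log10 >= 0)")
        if self.unfolding is not None and len(self.unfolding.log10_pf_open) != len(self.log10_pf):
            raise ValueError("open-state profile length must match folded profile")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a continuous-labelling experiment.

    ``replicate_schedule`` maps exposure (s) to replicate count; timepoints
    absent from the mapping get ``default_replicates``.  Designating a subset
    of timepoints for triplicates mirrors common practice where only selected
    exposures are run three times and those feed the replicate statistics.
    """

    states: tuple[str, ...]
    conditions: dict[str, LabellingCondition]
    timepoints: tuple[float, ...]
    replicate_schedule: dict[float, int] = field(default_factory=dict)
    default_replicates: int = 1
    noise_sd: float = 0.05
    back_exchange_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tps)
        if any(t <= 0 for t in tps) or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing and positive")
        if self.default_replicates < 1 or any(n < 1 for n in self.replicate_schedule.values()):
            raise ValueError("replicate counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.back_exchange_frac < 1.0:
            raise ValueError("back_exchange_frac must be in [0, 1)")
        missing = [s for s in self.states if s not in self.conditions]
        if missing:
            raise ValueError(f"no labelling condition for state(s): {missing}")

    def replicates_at(self, t: float) -> int:
        return self.replicate_schedule.get(float(t), self.default_replicates)


def random_protein_sequence(length: int, seed: int, proline_frac: float = 0.05) -> str:
    """A synthetic protein sequence with a realistic sprinkling of prolines.

    Stand-in for real sequences (which this package never ships); the first
    residue is forced to methionine.
    """
    rng = np.random.default_rng(seed)
    seq = ["M"]
    for _ in range(length - 1):
        seq.append("P" if rng.random() < proline_frac else _AA[rng.integers(len(_AA))])
    return "".join(seq)


def random_exchange_model(
    sequence: str,
    seed: int,
    reference_pH: float = 7.4,
    log10_rate_range: tuple[float, float] = (-0.5, 1.5),
) -> ResidueExchangeModel:
    """Random per-residue intrinsic rates, log-uniform over ``log10_rate_range``.

    The default range (0.3-30 /s) brackets typical unprotected-amide rates
    near neutral pH; absolute values are inconsequential downstream because
    only rate ratios are consumed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = log10_rate_range
    k = 10.0 ** rng.uniform(lo, hi, size=len(sequence))
    k[0] = 0.0
    k[[i for i, aa in enumerate(sequence) if aa == "P"]] = 0.0
    return ResidueExchangeModel(sequence, k, reference_pH)


def uniform_state(
    name: str,
    length: int,
    log10_pf: float,
    unfolding: Unfolding | None = None,
) -> ConformationalState:
    """Convenience constructor for a flat protection profile."""
    return ConformationalState(name, np.full(length, float(log10_pf)), unfolding)


def generate_peptide_map(
    sequence: str,
    mean_length: int = 12,
    overlap: int = 5,
    coverage_target: float = 0.9,
    seed: int = 0,
    protein_id: str = "synthetic",
) -> list[PeptideRecord]:
    """Tile a protein with overlapping proteolytic-style peptides.

    Peptide lengths jitter around ``mean_length``; consecutive peptides share
    roughly ``overlap`` residues.  A terminal fragment shorter than the
    overlap is absorbed into its predecessor.  If the achieved residue
    coverage falls short of ``coverage_target`` a warning is raised and the
    best-effort map returned.  Deterministic for a fixed seed.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not 0.0 < coverage_target <= 1.0:
        raise ValueError(f"coverage_target must be in (0, 1], got {coverage_target}")
    length = len(sequence)
    rng = np.random.default_rng(seed)
    peptides: list[PeptideRecord] = []
    start = 1
    while start <= length:
        jitter = int(rng.integers(-2, 3))
        pep_len = max(3, mean_length + jitter)
        end = min(start + pep_len - 1, length)
        if length - end < max(3, overlap):
            end = length  # absorb a too-short terminal fragment
        peptides.append(
            PeptideRecord(protein_id, sequence[start - 1 : end], start, end)
        )
        if end == length:
            break
        step = max(1, (end - start + 1) - overlap)
        start += step
    covered = set()
    for pep in peptides:
        covered.update(range(pep.start, pep.end + 1))
    achieved = len(covered) / length
    if achieved < coverage_target:
        warnings.warn(
            f"peptide map covers {achieved:.1%} of the sequence, below the "
            f"target {coverage_target:.1%}; returning best-effort map",
            stacklevel=2,
        )
    return peptides


def _observed_rates(
    peptide: PeptideRecord,
    model: ResidueExchangeModel,
    log10_pf: np.ndarray,
    pH: float | None,
) -> np.ndarray:
    if peptide.end > len(model.sequence):
        raise ValueError("peptide extends beyond the modelled sequence")
    k = model.k_int_ref if pH is None else model.rates_at(pH)
    # The peptide's own first residue never retains label (fast back
    # exchange of the N-terminal amine region), so it is excluded exactly as
    # in the exchangeable-amide count.
    idx = slice(peptide.start, peptide.end)  # 0-based start+1 .. end
    return k[idx] / 10.0 ** np.asarray(log10_pf, dtype=float)[idx]


def ex2_uptake(
    peptide: PeptideRecord,
    model: ResidueExchangeModel,
    state: ConformationalState,
    t: float,
    d_frac: float,
    pH: float | None = None,
    open_state: bool = False,
) -> float:
    """Expected EX2 deuterium content of a peptide after ``t`` seconds.

    Returns ``d_frac * sum_i (1 - exp(-k_int_i / 10**pf_i * t))`` over the
    peptide's exchangeable residues.  ``pH`` defaults to the model's
    reference pH; ``open_state`` selects the open-state protection profile
    of an unfoldable conformational state.
    """
    if t < 0:
        raise ValueError(f"labelling time must be non-negative, got {t}")
    if open_state:
        if state.unfolding is None:
            raise ValueError(f"state {state.name!r} has no unfolding parameters")
        pf = state.unfolding.log10_pf_open
    else:
        pf = state.log10_pf
    k_obs = _observed_rates(peptide, model, pf, pH)
    return float(d_frac * np.sum(-np.expm1(-k_obs * t)))


def simulate_two_state(state: ConformationalState, t_preincubation: float) -> tuple[float, float]:
    """Population weights (folded, open) after irreversible pre-incubation.

    ``w_open = 1 - exp(-k_open * t)``; no refolding term.
    """
    if state.unfolding is None:
        raise ValueError(f"state {state.name!r} has no unfolding parameters")
    w_open = -np.expm1(-state.unfolding.k_open * t_preincubation)
    return 1.0 - w_open, float(w_open)


def simulate_dataset(
    design: ExperimentDesign,
    model: ResidueExchangeModel,
    peptides: list[PeptideRecord],
    states: dict[str, ConformationalState],
    control_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full uptake table plus maximally labelled control table.

    Each (peptide, state, timepoint, replicate) gets
    ``ex2_uptake * (1 - back_exchange_frac) + N(0, noise_sd)``; controls are
    ``d_frac * n_exchangeable * (1 - back_exchange_frac) + noise``.
    Reproducible for a fixed design seed.
    """
    missing = [s for s in design.states if s not in states]
    if missing:
        raise ValueError(f"no ConformationalState supplied for: {missing}")
    rng = np.random.default_rng(design.seed)
    retain = 1.0 - design.back_exchange_frac

    rows = []
    for state_name in design.states:
        state = states[state_name]
        cond = design.conditions[state_name]
        for pep in peptides:
            for t in design.timepoints:
                expected = retain * ex2_uptake(
                    pep, model, state, t, cond.d_frac, pH=cond.pH_read
                )
                for rep in range(1, design.replicates_at(t) + 1):
                    value = expected + rng.normal(0.0, design.noise_sd) if design.noise_sd else expected
                    rows.append(
                        (pep.protein_id, pep.start, pep.end, pep.sequence,
                         state_name, t, rep, value)
                    )
    uptake = pd.DataFrame(
        rows,
        columns=["protein", "start", "end", "sequence", "state", "exposure_s", "replicate", "uptake_Da"],
    )

    ctrl_rows = []
    for state_name in design.states:
        cond = design.conditions[state_name]
        for pep in peptides:
            expected = retain * cond.d_frac * pep.n_exchangeable
            for rep in range(1, control_replicates + 1):
                value = expected + rng.normal(0.0, design.noise_sd) if design.noise_sd else expected
                ctrl_rows.append(
                    (pep.protein_id, pep.start, pep.end, pep.sequence,
                     state_name, CONTROL_EXPOSURE_S, rep, value)
                )
    controls = pd.DataFrame(ctrl_rows, columns=list(uptake.columns))
    return uptake, controls
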