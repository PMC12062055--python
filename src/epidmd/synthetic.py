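"""Synthetic incidence panels from a known low-rank linear dynamical system.

County-level cancer-registry data are distributed under data-use agreements
and cannot ship with the package, so every downstream stage is exercised on
panels drawn from the same generative form the decomposition assumes:

    x_k = Re( sum_j  phi_j  lambda_j^(k-1)  b_j ) + eps_k,
    eps_k ~ N(0, noise_sd^2) i.i.d.,

with a conjugate-closed eigenvalue set so the noise-free state is real. The
ground truth (eigenvalues, modes, amplitudes) is retained in
:class:`SyntheticTruth`, giving exact parameter-recovery oracles.

The default configuration emulates the structure of a national county panel:
~1,000 counties observed over 22 annual snapshots, an overall level around
65 per 100,000 decaying slowly (dominant real eigenvalue just inside the
unit circle), a smaller oscillatory conjugate pair, spatially clustered
high/low blocks (one pseudo-state's dominant-mode loading inflated, another
deflated — the "high-incidence state / low-incidence state" pattern), and
additive Gaussian observation noise. Counties receive block-structured
synthetic FIPS codes whose first two digits identify the pseudo-state, so
state-level aggregation logic is exercisable.

The positive baseline that keeps rates non-negative is carried by the
dominant decaying mode itself (all-positive loadings) rather than by an
additive constant: a constant offset would be an extra lambda=1 mode and
would break the exact-rank and eigenvalue-recovery guarantees. An explicit
additive ``offset`` is available for experiments that want one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_panel import IncidencePanel

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_panel",
    "inject_missing",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic panel generator.

    ``eigenvalues`` is a sequence of (magnitude, frequency) pairs; frequency
    0 contributes one real mode, frequency != 0 a conjugate pair (two modes).
    The implied true rank ``r_true`` is the total mode count.
    """

    n_counties: int = 1000
    n_years: int = 22
    #: (magnitude, angular frequency per year) per generating eigenvalue.
    eigenvalues: tuple[tuple[float, float], ...] = ((0.97, 0.0), (0.9, 0.6))
    n_blocks: int = 50
    #: Pseudo-state (2-digit FIPS prefix) whose dominant-mode loading is inflated.
    high_block: str = "21"
    low_block: str = "06"
    high_multiplier: float = 3.0
    low_multiplier: float = 0.5
    #: Mean rate (per 100,000) carried by the dominant mode at the first year.
    base_rate: float = 65.0
    #: Relative spread of dominant-mode loadings across counties.
    loading_jitter: float = 0.25
    #: Typical per-county amplitude (rate units) of non-dominant modes.
    osc_scale: float = 3.0
    noise_sd: float = 2.0
    #: Additive constant offset (rate units); 0 keeps the exact low-rank form.
    offset: float = 0.0
    missing_fraction: float = 0.0
    clip_negative: bool = False
    seed: int = 7

    @property
    def r_true(self) -> int:
        return sum(1 if f == 0.0 else 2 for _, f in self.eigenvalues)

    def validate(self) -> None:
        if self.n_counties < 1 or self.n_years < 2:
            raise ValidationError("need n_counties >= 1 and n_years >= 2")
        if not self.eigenvalues:
            raise ValidationError("at least one generating eigenvalue required")
        if any(mag > 1.05 or mag <= 0 for mag, _ in self.eigenvalues):
            raise ValidationError("eigenvalue magnitudes must be in (0, 1.05]")
        if not 1 <= self.r_true <= min(self.n_counties, self.n_years - 1):
            raise ValidationError(
                f"r_true={self.r_true} outside [1, min(n, m-1)="
                f"{min(self.n_counties, self.n_years - 1)}]"
            )
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_blocks < 1 or self.n_blocks > 99:
            raise ValidationError("n_blocks must be in [1, 99]")


@dataclass
class SyntheticTruth:
    """Generating parameters behind a simulated panel.

    ``eigenvalues[j]``, ``modes[:, j]`` and ``amplitudes[j]`` describe mode j;
    non-real eigenvalues appear in conjugate pairs with conjugate modes and
    amplitudes, so the noise-free state is real. Mode columns are unit-norm.
    """

    eigenvalues: np.ndarray  # (r_true,) complex
    modes: np.ndarray = field(repr=False)  # (n, r_true) complex, unit columns
    amplitudes: np.ndarray  # (r_true,) complex
    noise_sd: float
    seed: int
    block_assignment: dict[str, str]  # fips -> block label

    def noise_free_state(self, k: int) -> np.ndarray:
        """The exact state x_k (1-based snapshot index), before noise."""
        coeff = self.amplitudes * self.eigenvalues ** (k - 1)
        state = self.modes @ coeff
        if np.abs(state.imag).max(initial=0.0) > 1e-10:
            raise ValidationError("truth is not conjugate-closed; state not real")
        return state.real

    def to_json(self, path) -> None:
        payload = {
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "amplitudes": [[z.real, z.imag] for z in self.amplitudes],
            "modes_real": self.modes.real.tolist(),
            "modes_imag": self.modes.imag.tolist(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "block_assignment": self.block_assignment,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            eigenvalues=np.array([complex(a, b) for a, b in p["eigenvalues"]]),
            modes=np.array(p["modes_real"]) + 1j * np.array(p["modes_imag"]),
            amplitudes=np.array([complex(a, b) for a, b in p["amplitudes"]]),
            noise_sd=p["noise_sd"],
            seed=p["seed"],
            block_assignment=p["block_assignment"],
        )


def _synthetic_fips(cfg: GeneratorConfig) -> tuple[list[str], dict[str, str]]:
    """Block-structured 5-digit codes: 2-digit block + 3-digit county index."""
    per_block = math.ceil(cfg.n_counties / cfg.n_blocks)
    fips, blocks = [], {}
    for i in range(cfg.n_counties):
        block = f"{(i // per_block) + 1:02d}"
        code = f"{block}{(i % per_block) + 1:03d}"
        fips.append(code)
        blocks[code] = block
    return fips, blocks


def generate_panel(cfg: GeneratorConfig) -> tuple[IncidencePanel, SyntheticTruth]:
    """Simulate a county-by-year rate panel with known modal structure.

    Deterministic given ``cfg.seed``. Returns the (possibly incomplete, if
    ``missing_fraction > 0``) panel together with the generating truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_counties, cfg.n_years
    fips, blocks = _synthetic_fips(cfg)

    eigs: list[complex] = []
    mode_cols: list[np.ndarray] = []
    amps: list[complex] = []
    for j, (mag, freq) in enumerate(cfg.eigenvalues):
        if freq == 0.0:
            lam = complex(mag, 0.0)
            if j == 0:
                # Dominant mode: positive loadings carrying the baseline level,
                # with block multipliers producing the high/low geography.
                raw = 1.0 + cfg.loading_jitter * rng.random(n)
                mult = np.ones(n)
                mult[[blocks[f] == cfg.high_block for f in fips]] = cfg.high_multiplier
                mult[[blocks[f] == cfg.low_block for f in fips]] = cfg.low_multiplier
                raw *= mult
                target = cfg.base_rate * raw / raw.mean()
                norm = np.linalg.norm(target)
                phi = (target / norm).astype(complex)
                b = complex(norm, 0.0)
            else:
                v = rng.standard_normal(n)
                phi = (v / np.linalg.norm(v)).astype(complex)
                b = complex(cfg.osc_scale * math.sqrt(n), 0.0)
            eigs.append(lam)
            mode_cols.append(phi)
            amps.append(b)
        else:
            lam = mag * complex(math.cos(freq), math.sin(freq))
            v = rng.standard_normal(n) + 1j * rng.standard_normal(n)
            phi = v / np.linalg.norm(v)
            theta = rng.uniform(0, 2 * math.pi)
            b = 0.5 * cfg.osc_scale * math.sqrt(n) * complex(
                math.cos(theta), math.sin(theta)
            )
            eigs.extend([lam, lam.conjugate()])
            mode_cols.extend([phi, phi.conjugate()])
            amps.extend([b, b.conjugate()])

    eigenvalues = np.array(eigs)
    modes = np.column_stack(mode_cols)
    amplitudes = np.array(amps)

    # x_k = Re(Phi diag(lambda)^(k-1) b), columns k = 1..m.
    powers = eigenvalues[:, None] ** np.arange(m)[None, :]  # (r, m)
    states = modes @ (powers * amplitudes[:, None])  # (n, m) complex
    if np.abs(states.imag).max() > 1e-9 * max(np.abs(states.real).max(), 1.0):
        raise ValidationError("conjugate pairing failed; non-real states")
    values = states.real + cfg.offset
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=(n, m))
    if cfg.clip_negative:
        values = np.clip(values, 0.0, None)

    first_year = 2000
    panel = IncidencePanel(
        counties=fips,
        years=list(range(first_year, first_year + m)),
        values=values,
    )
    truth = SyntheticTruth(
        eigenvalues=eigenvalues,
        modes=modes,
        amplitudes=amplitudes,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
        block_assignment=blocks,
    )
    if cfg.missing_fraction > 0:
        panel, _ = inject_missing(panel, cfg.missing_fraction, cfg.seed + 1)
    return panel, truth


def inject_missing(
    panel: IncidencePanel, fraction: float, seed: int
) -> tuple[IncidencePanel, list[str]]:
    """Blank out >= 1 year in ``floor(fraction * n)`` counties, reproducibly.

    Emulates registry suppression so the complete-case filter has something
    to drop. Returns the degraded panel and the sorted FIPS codes affected.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must be in [0, 1)")
    n, m = panel.n_counties, panel.n_years
    k = int(fraction * n)
    if k == 0:
        return panel, []
    rng = np.random.default_rng(seed)
    hit = rng.choice(n, size=k, replace=False)
    values = panel.values.copy()
    for i in hit:
        n_gone = int(rng.integers(1, min(3, m) + 1))
        cols = rng.choice(m, size=n_gone, replace=False)
        values[i, cols] = np.nan
    degraded = IncidencePanel(
        counties=list(panel.counties), years=list(panel.years), values=values
    )
    return degraded, sorted(panel.counties[i] for i in hit)
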