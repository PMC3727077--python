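"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis: every parameter is varied
simultaneously along a space-filling search curve

    x_j(s) = G_j( 1/2 + arcsin(sin(w_j s + phi_j)) / pi ),   s in (-pi, pi],

where the parameter of interest carries a high frequency w_i and the
complementary set low, non-interfering frequencies. The output spectrum is
decomposed by discrete Fourier coefficients A_p, B_p:

    D_i     = 2 sum_{p=1..M} ( A_{p w_i}^2 + B_{p w_i}^2 )        (partial)
    D_total = 2 sum_{j>=1}   ( A_j^2 + B_j^2 )                     (total)
    S_i     = D_i / D_total                                        (first order)
    S_Ti    = 1 - D_ci / D_total                                   (total order)

with D_ci the variance at the low frequencies (j <= w_i / 2) attributable to
the complementary set. Indices are averaged over N_r random-phase resample
curves. First-order indices ignore interactions; S_Ti - S_i measures how much
a parameter matters only in combination with others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EfastDesign",
    "EfastResult",
    "sample_search_curve",
    "partial_variance",
    "total_variance",
    "indices",
    "efast",
    "run_module_analysis",
    "MODULE_GROUPS",
]


@dataclass(frozen=True)
class EfastDesign:
    """Sampling design for one eFAST analysis.

    n_samples must satisfy the Nyquist-type condition
    n_samples >= 4 * harmonics * omega_i + 1; the complementary frequencies
    are kept at or below omega_i / (2 * harmonics) so their first
    ``harmonics`` harmonics cannot collide with those of omega_i.
    """

    ranges: tuple[tuple[float, float], ...]  # (lo, hi) per parameter
    n_samples: int = 257
    harmonics: int = 4  # M
    n_resamples: int = 5  # N_r
    log_scale: bool = False  # map the curve through log10-uniform ranges

    def __post_init__(self) -> None:
        for lo, hi in self.ranges:
            if not (hi > lo):
                raise ValueError("each range must satisfy hi > lo")
            if self.log_scale and lo <= 0:
                raise ValueError("log-scale design requires positive ranges")
        if self.omega_i < 1:
            raise ValueError(
                f"n_samples={self.n_samples} too small for M={self.harmonics}: "
                "Nyquist condition n_samples >= 4*M*omega + 1 unsatisfiable"
            )

    @property
    def k(self) -> int:
        return len(self.ranges)

    @property
    def omega_i(self) -> int:
        """Frequency assigned to the parameter of interest."""
        return (self.n_samples - 1) // (4 * self.harmonics)

    @property
    def omega_complementary_max(self) -> int:
        return max(1, self.omega_i // (2 * self.harmonics))


def _frequencies(design: EfastDesign, i: int) -> np.ndarray:
    """Frequency vector: omega_i for parameter i, spread low ones elsewhere.

    Complementary frequencies are taken as high as the interference bound
    allows (<= omega_i / 2M) and spread downward, preferring values that do
    not divide omega_i so that their higher harmonics cannot alias onto the
    harmonics of the parameter of interest. Low frequencies like {1, 2} would
    make the complementary sub-curve too degenerate to express interaction
    variance, biasing D_total low.
    """
    w = np.empty(design.k, dtype=int)
    wc_max = design.omega_complementary_max
    wi = design.omega_i
    candidates = [v for v in range(wc_max, 0, -1) if wi % v != 0]
    candidates += [v for v in range(wc_max, 0, -1) if wi % v == 0]
    c = 0
    for j in range(design.k):
        if j == i:
            w[j] = wi
        else:
            w[j] = candidates[c % len(candidates)]
            c += 1
    return w


def sample_search_curve(
    design: EfastDesign, i: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Parameter matrix (n_samples x k) and the curve variable s.

    Marginals of each column are uniform (or log-uniform) over the declared
    range; deterministic for a seeded generator (phases are the only
    randomness).
    """
    if not 0 <= i < design.k:
        raise ValueError("parameter index out of range")
    rng = rng or np.random.default_rng(0)
    n = design.n_samples
    s = np.pi * (2.0 * np.arange(1, n + 1) - n - 1.0) / n  # uniform in (-pi, pi]
    w = _frequencies(design, i)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=design.k)
    x = np.empty((n, design.k))
    for j in range(design.k):
        g = 0.5 + np.arcsin(np.sin(w[j] * s + phi[j])) / np.pi
        lo, hi = design.ranges[j]
        if design.log_scale:
            x[:, j] = lo * (hi / lo) ** g
        else:
            x[:, j] = lo + (hi - lo) * g
    return x, s


def _fourier_coefficients(y: np.ndarray, s: np.ndarray, freqs: np.ndarray):
    """Mean-normalized cosine/sine coefficients A_j, B_j at given frequencies."""
    yc = y - y.mean()
    A = np.array([np.mean(yc * np.cos(j * s)) for j in freqs])
    B = np.array([np.mean(yc * np.sin(j * s)) for j in freqs])
    return A, B


def partial_variance(y: np.ndarray, s: np.ndarray, omega: int, harmonics: int) -> float:
    """D_i: twice the summed squared Fourier coefficients at p*omega, p=1..M."""
    n = len(y)
    if n < 4 * harmonics * omega + 1:
        raise ValueError(
            f"{n} samples cannot resolve {harmonics} harmonics of frequency {omega}"
        )
    freqs = omega * np.arange(1, harmonics + 1)
    A, B = _fourier_coefficients(y, s, freqs)
    return float(2.0 * np.sum(A**2 + B**2))


def total_variance(y: np.ndarray, s: np.ndarray) -> float:
    """D_total: twice the summed squared coefficients over the full spectrum."""
    n = len(y)
    freqs = np.arange(1, (n - 1) // 2 + 1)
    A, B = _fourier_coefficients(y, s, freqs)
    return float(2.0 * np.sum(A**2 + B**2))


def indices(d_i: float, d_ci: float, d_total: float) -> tuple[float, float]:
    """(S_i, S_Ti) from the partial, complementary and total variances."""
    if d_total <= 0.0:
        return float("nan"), float("nan")
    return d_i / d_total, 1.0 - d_ci / d_total


@dataclass
class EfastResult:
    parameters: list
    outputs: list
    s_first: pd.DataFrame  # rows: parameters, cols: outputs
    s_total: pd.DataFrame
    design: EfastDesign

    def to_frame(self, module: str = "") -> pd.DataFrame:
        rows = []
        for p in self.parameters:
            for o in self.outputs:
                rows.append(
                    (module, p, o, self.s_first.loc[p, o], self.s_total.loc[p, o])
                )
        return pd.DataFrame(rows, columns=["module", "parameter", "output", "S_i", "S_Ti"])


def efast(
    func: Callable[[np.ndarray], np.ndarray],
    design: EfastDesign,
    seed: int = 0,
    parameter_names: Sequence[str] | None = None,
    output_names: Sequence[str] | None = None,
) -> EfastResult:
    """Run eFAST on a vector-valued model ``func(x) -> outputs``.

    ``func`` receives one parameter vector (length k) and returns one or more
    outputs; indices are computed per output and averaged over
    ``design.n_resamples`` random-phase curves.
    """
    rng = np.random.default_rng(seed)
    probe = np.atleast_1d(np.asarray(func(sample_search_curve(design, 0, rng)[0][0])))
    n_out = probe.size
    parameter_names = list(parameter_names or [f"x{j}" for j in range(design.k)])
    output_names = list(output_names or [f"y{j}" for j in range(n_out)])

    s_first = np.zeros((design.k, n_out))
    s_total = np.zeros((design.k, n_out))
    m = design.harmonics
    w_low = design.omega_i // 2  # complementary band for S_Ti
    for i in range(design.k):
        acc_first = np.zeros(n_out)
        acc_total = np.zeros(n_out)
        for _ in range(design.n_resamples):
            x, s = sample_search_curve(design, i, rng)
            y = np.array([np.atleast_1d(func(row)) for row in x])  # (n, n_out)
            for o in range(n_out):
                d_i = partial_variance(y[:, o], s, design.omega_i, m)
                d_tot = total_variance(y[:, o], s)
                freqs = np.arange(1, w_low + 1)
                A, B = _fourier_coefficients(y[:, o], s, freqs)
                d_ci = float(2.0 * np.sum(A**2 + B**2))
                si, sti = indices(d_i, d_ci, d_tot)
                acc_first[o] += si
                acc_total[o] += sti
        s_first[i] = acc_first / design.n_resamples
        s_total[i] = acc_total / design.n_resamples
    return EfastResult(
        parameters=parameter_names,
        outputs=output_names,
        s_first=pd.DataFrame(s_first, index=parameter_names, columns=output_names),
        s_total=pd.DataFrame(s_total, index=parameter_names, columns=output_names),
        design=design,
    )


# ---------------------------------------------------------------------------
# modular analysis of the compartment model

#: default parameter groupings for the modular analysis (editable): receptor
#: expression on tumor cells, transport, and kinetic rate constants.
MODULE_GROUPS: dict[str, list[str]] = {
    "receptor": [
        "network.surfaces.tumor_cell.receptors_per_cell.R1",
        "network.surfaces.tumor_cell.receptors_per_cell.R2",
        "network.surfaces.tumor_cell.receptors_per_cell.N1",
        "network.surfaces.tumor_cell.receptors_per_cell.N2",
    ],
    "transport": [
        "transport.permeability_cm_per_s.normal.V",
        "transport.permeability_cm_per_s.tumor.V",
        "transport.permeability_cm_per_s.normal.sR1",
        "transport.lymph_flow_cm3_per_s_per_cm3.normal",
        "transport.clearance_per_s.V",
    ],
    "kinetic": [
        "kinetics.V:R1.kon_per_M_s",
        "kinetics.V:R2.kon_per_M_s",
        "kinetics.V:NRP.kon_per_M_s",
        "kinetics.sR1:V.kon_per_M_s",
        "kinetics.V:GAG.kon_per_M_s",
    ],
}

DEFAULT_OUTPUTS = [
    "vegf_mouse_normal", "vegf_mouse_blood", "vegf_mouse_tumor",
    "vegf_human_normal", "vegf_human_blood", "vegf_human_tumor",
    "svegfr1_normal", "svegfr1_blood", "svegfr1_tumor",
]


def run_module_analysis(
    base_config: dict,
    module: str,
    outputs: Sequence[str] | None = None,
    groups: dict[str, list[str]] | None = None,
    n_samples: int = 65,
    harmonics: int = 4,
    n_resamples: int = 1,
    range_decades: float = 1.0,
    seed: int = 0,
) -> EfastResult:
    """eFAST of steady-state VEGF/sVEGFR1 concentrations for one parameter module.

    Each parameter in the module's group is varied log-uniformly within
    ``range_decades`` orders of magnitude around its baseline value; the model
    outputs are drug-free steady-state concentrations.
    """
    from .config import get_param
    from .engine import CompiledModel

    groups = groups or MODULE_GROUPS
    if module not in groups:
        raise ValueError(f"unknown module {module!r}; have {sorted(groups)}")
    paths = groups[module]
    if not paths:
        raise ValueError(f"module {module!r} has an empty parameter group")
    outputs = list(outputs or DEFAULT_OUTPUTS)

    base_model = CompiledModel.from_config(base_config)
    baselines = [float(get_param(base_config, p)) for p in paths]
    scale = 10.0**range_decades
    ranges = tuple((b / scale, b * scale) for b in baselines)
    design = EfastDesign(
        ranges=ranges,
        n_samples=n_samples,
        harmonics=harmonics,
        n_resamples=n_resamples,
        log_scale=True,
    )
    warm: dict = {"y": None}

    def evaluate(x: np.ndarray) -> np.ndarray:
        model = base_model.with_params(dict(zip(paths, x)))
        y = model.steady_state(y0=warm["y"])
        warm["y"] = y
        return np.array([y[model._obs[name]].sum() for name in outputs])

    return efast(evaluate, design, seed=seed,
                 parameter_names=paths, output_names=outputs)
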