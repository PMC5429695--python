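"""Single-site (1:1) isothermal titration calorimetry: model, simulation, fit.

The model follows the standard perfusion-cell convention: each injection of
volume dv displaces cell content, multiplying existing concentrations by
(1 - dv/V0) before the titrant is added.  After injection i the bound
concentration B_i is the smaller root of the mass-action quadratic

    Ka * (n*Mt_i - B) * (Lt_i - B) = B

and the observed differential heat is

    q_i = Q_i - Q_{i-1} + (dv_i/V0) * (Q_i + Q_{i-1}) / 2 + q_offset

with cumulative heat Q_i = B_i * dH * V0 (in µcal).  Fitting is nonlinear
least squares over (n, ln Ka, dH, q_offset), with Ka on a log scale to
enforce positivity.  Derived quantities use the thermodynamic identities
dG = -R*T*ln(Ka) and TdS = dH - dG with R = 1.9872e-3 kcal/(mol*K).

Binding experiments on cohesin-dockerin pairs are conventionally run at
308 K (rumen temperature), which is the default here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ParseError, ProtocolError

R_KCAL = 1.9872e-3          # kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 308.0  # K
DEFAULT_CELL_VOLUME = 1.4195e-3  # L (standard perfusion cell)
KCAL_TO_UCAL = 1.0e9


@dataclass
class ItcProtocol:
    """Titration schedule and cell composition."""

    cell_volume: float = DEFAULT_CELL_VOLUME   # L
    temperature: float = DEFAULT_TEMPERATURE   # K
    cell_conc: float = 1.0e-6                  # M macromolecule in cell (Mt0)
    syringe_conc: float = 1.5e-5               # M titrant in syringe (Lt0)
    injection_volumes: tuple[float, ...] = (10e-6,) * 28  # L each
    injection_spacing: float = 220.0           # s, metadata only

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_conc, self.syringe_conc) <= 0:
            raise ProtocolError("volumes and concentrations must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ProtocolError("injection volumes must be positive")
        if sum(self.injection_volumes) >= self.cell_volume:
            raise ProtocolError(
                "total injected volume exceeds the cell volume "
                f"({sum(self.injection_volumes):.2e} >= {self.cell_volume:.2e} L)"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class ThermoParams:
    """Single-site binding parameters."""

    n: float = 1.0        # sites per macromolecule
    Ka: float = 1.0e7     # M^-1
    dH: float = -50.0     # kcal/mol
    q_offset: float = 0.0  # µcal per injection (dilution heat)
    n_se: float | None = None
    Ka_se: float | None = None
    dH_se: float | None = None
    q_offset_se: float | None = None

    def __post_init__(self) -> None:
        if self.Ka <= 0 or self.n <= 0:
            raise ValueError("Ka and n must be positive")


@dataclass
class ItcDataset:
    protocol: ItcProtocol
    heats: np.ndarray          # µcal, one value per injection
    seed: int | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != self.protocol.n_injections:
            raise ValueError("heats length must match the injection count")


@dataclass
class ItcFit:
    params: ThermoParams
    dG: float                 # kcal/mol, -R*T*ln(Ka)
    TdS: float                # kcal/mol, dH - dG
    residual_rms: float       # µcal
    converged: bool
    ill_conditioned: bool = False   # Wiseman c above 1e4
    n_iterations: int = 0


def totals_after_injections(protocol: ItcProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Diluted cell totals (Mt_i, Lt_i) after each injection."""
    V0 = protocol.cell_volume
    Mt = np.empty(protocol.n_injections)
    Lt = np.empty(protocol.n_injections)
    m, lig = protocol.cell_conc, 0.0
    for i, dv in enumerate(protocol.injection_volumes):
        f = 1.0 - dv / V0
        m *= f
        lig = lig * f + protocol.syringe_conc * dv / V0
        Mt[i], Lt[i] = m, lig
    return Mt, Lt


def bound_concentration(Ka: float, n: float, Mt: np.ndarray, Lt: np.ndarray) -> np.ndarray:
    """Smaller root of Ka*(n*Mt - B)*(Lt - B) = B, stably evaluated."""
    nMt = n * np.asarray(Mt, dtype=float)
    Lt = np.asarray(Lt, dtype=float)
    b = Ka * (nMt + Lt) + 1.0
    disc = b * b - 4.0 * Ka * Ka * nMt * Lt
    disc = np.maximum(disc, 0.0)
    # smaller root via the numerically stable form 2c / (b + sqrt(disc))
    B = 2.0 * Ka * nMt * Lt / (b + np.sqrt(disc))
    if np.any(B < -1e-12) or np.any(B > np.minimum(nMt, Lt) * (1 + 1e-9) + 1e-30):
        raise ArithmeticError("non-physical bound-concentration root")
    return B


def model_heats(protocol: ItcProtocol, params: ThermoParams) -> np.ndarray:
    """Per-injection differential heats in µcal for the 1:1 model."""
    Mt, Lt = totals_after_injections(protocol)
    B = bound_concentration(params.Ka, params.n, Mt, Lt)
    V0 = protocol.cell_volume
    Q = B * params.dH * V0 * KCAL_TO_UCAL  # cumulative µcal
    q = np.empty(protocol.n_injections)
    prev = 0.0
    for i, dv in enumerate(protocol.injection_volumes):
        q[i] = Q[i] - prev + (dv / V0) * (Q[i] + prev) / 2.0 + params.q_offset
        prev = Q[i]
    return q


def simulate_titration(
    protocol: ItcProtocol,
    params: ThermoParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ItcDataset:
    """Model heats plus i.i.d. Gaussian noise (µcal); reproducible by seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    heats = model_heats(protocol, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return ItcDataset(protocol=protocol, heats=heats, seed=seed)


def _initial_guess(dataset: ItcDataset) -> ThermoParams:
    protocol = dataset.protocol
    Mt, Lt = totals_after_injections(protocol)
    moles_per_injection = protocol.syringe_conc * np.array(protocol.injection_volumes)
    peak = dataset.heats[np.argmax(np.abs(dataset.heats))]
    idx = int(np.argmax(np.abs(dataset.heats)))
    dH0 = (peak / KCAL_TO_UCAL) / moles_per_injection[idx]
    dH0 = float(np.clip(dH0, -500, 500)) or -1.0
    # steepest heat change marks the equivalence region; seed Ka at c ~ 50
    slopes = np.abs(np.diff(dataset.heats))
    i_steep = int(np.argmax(slopes)) if len(slopes) else 0
    Ka0 = 50.0 / max(Mt[i_steep], 1e-12)
    return ThermoParams(n=1.0, Ka=Ka0, dH=dH0, q_offset=0.0)


def fit_single_site(
    dataset: ItcDataset,
    init: ThermoParams | None = None,
    exclude_first: bool = False,
) -> ItcFit:
    """Nonlinear least-squares fit of the single-site model.

    Fits (n, ln Ka, dH, q_offset); standard errors come from the residual
    covariance at the optimum.  ``exclude_first`` drops injection 1 from the
    residuals (a common instrument convention, off by default).
    """
    if dataset.protocol.n_injections < 6:
        raise ProtocolError("need at least 6 injections to fit a binding model")
    init = init or _initial_guess(dataset)
    mask = np.ones(dataset.protocol.n_injections, dtype=bool)
    if exclude_first:
        mask[0] = False
    observed = dataset.heats

    def residuals(x):
        n, ln_ka, dH, q0 = x
        try:
            model = model_heats(
                dataset.protocol,
                ThermoParams(n=n, Ka=float(np.exp(ln_ka)), dH=dH, q_offset=q0),
            )
        except (ArithmeticError, ValueError):
            return np.full(mask.sum(), 1e6)
        return (model - observed)[mask]

    x0 = np.array([init.n, np.log(init.Ka), init.dH, init.q_offset])
    best = None
    for ka_scale in (1.0, 1e2, 1e-2):
        start = x0.copy()
        start[1] = x0[1] + np.log(ka_scale)
        sol = least_squares(
            residuals,
            start,
            bounds=([1e-3, np.log(1.0), -np.inf, -np.inf], [100.0, np.log(1e18), np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
        if best.cost < 1e-20:
            break
    sol = best
    n_fit, ln_ka, dH_fit, q0_fit = sol.x
    Ka_fit = float(np.exp(ln_ka))
    m = int(mask.sum())
    dof = max(m - 4, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    params = ThermoParams(
        n=float(n_fit),
        Ka=Ka_fit,
        dH=float(dH_fit),
        q_offset=float(q0_fit),
        n_se=float(se[0]),
        Ka_se=float(Ka_fit * se[1]),
        dH_se=float(se[2]),
        q_offset_se=float(se[3]),
    )
    T = dataset.protocol.temperature
    dG, TdS = derive_thermodynamics(Ka_fit, float(dH_fit), T)
    c_value = params.n * params.Ka * dataset.protocol.cell_conc
    return ItcFit(
        params=params,
        dG=dG,
        TdS=TdS,
        residual_rms=float(np.sqrt(np.mean(residuals(sol.x) ** 2))),
        converged=bool(sol.success),
        ill_conditioned=bool(c_value > 1e4),
        n_iterations=int(sol.nfev),
    )


def derive_thermodynamics(Ka: float, dH: float, T: float = DEFAULT_TEMPERATURE):
    """dG = -R*T*ln(Ka) and TdS = dH - dG, in kcal/mol."""
    if Ka <= 0 or T <= 0:
        raise ValueError("Ka and T must be positive")
    dG = -R_KCAL * T * np.log(Ka)
    return float(dG), float(dH - dG)


def gibbs_from_enthalpy_entropy(dH: float, TdS: float) -> float:
    """dG from the identity dG = dH - TdS (kcal/mol)."""
    return dH - TdS


def protocol_for_c_value(
    params: ThermoParams,
    c_value: float = 100.0,
    syringe_ratio: float = 15.0,
    n_injections: int = 28,
    injection_volume: float = 10e-6,
    temperature: float = DEFAULT_TEMPERATURE,
    cell_volume: float = DEFAULT_CELL_VOLUME,
) -> ItcProtocol:
    """Protocol with the cell concentration set for a target Wiseman c.

    c = n * Ka * Mt0, so Mt0 = c / (n * Ka); the syringe holds
    ``syringe_ratio`` times the cell concentration.  Defaults reproduce the
    28 x 10 µL schedule used for cohesin-dockerin titrations.
    """
    cell_conc = c_value / (params.n * params.Ka)
    return ItcProtocol(
        cell_volume=cell_volume,
        temperature=temperature,
        cell_conc=cell_conc,
        syringe_conc=syringe_ratio * cell_conc,
        injection_volumes=(injection_volume,) * n_injections,
    )


# ---------------------------------------------------------------------------
# delimited-text round trip

ITC_COLUMNS = ("injection_index", "volume_uL", "heat_ucal")


def write_itc(dataset: ItcDataset, path: str | Path) -> None:
    """Write the tab-delimited format; protocol metadata in '#' header lines."""
    p = dataset.protocol
    lines = [
        f"# cell_volume_L={p.cell_volume!r}",
        f"# temperature_K={p.temperature!r}",
        f"# cell_conc_M={p.cell_conc!r}",
        f"# syringe_conc_M={p.syringe_conc!r}",
        f"# injection_spacing_s={p.injection_spacing!r}",
    ]
    frame = pd.DataFrame(
        {
            "injection_index": np.arange(1, p.n_injections + 1),
            "volume_uL": np.array(p.injection_volumes) * 1e6,
            "heat_ucal": dataset.heats,
        }
    )
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_itc(
    path: str | Path,
    cell_conc: float | None = None,
    syringe_conc: float | None = None,
    cell_volume: float | None = None,
    temperature: float | None = None,
) -> ItcDataset:
    """Read the delimited format; explicit arguments override header metadata."""
    path = Path(path)
    meta: dict[str, float] = {}
    body_lines = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            try:
                key, value = line.lstrip("# ").split("=")
                meta[key.strip()] = float(value)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad metadata line") from exc
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise ParseError(f"{path}: no data rows")
    try:
        frame = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: cannot parse delimited data: {exc}") from exc
    missing = [c for c in ITC_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for row_pos, row in frame.iterrows():
        if row[list(ITC_COLUMNS)].isna().any():
            raise ParseError(f"{path}: row {row_pos + 1}: non-numeric or missing value")
    protocol = ItcProtocol(
        cell_volume=cell_volume or meta.get("cell_volume_L", DEFAULT_CELL_VOLUME),
        temperature=temperature or meta.get("temperature_K", DEFAULT_TEMPERATURE),
        cell_conc=cell_conc or meta.get("cell_conc_M", 1.0e-6),
        syringe_conc=syringe_conc or meta.get("syringe_conc_M", 1.5e-5),
        injection_volumes=tuple(frame["volume_uL"].to_numpy() * 1e-6),
    )
    return ItcDataset(protocol=protocol, heats=frame["heat_ucal"].to_numpy())
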