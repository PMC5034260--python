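"""Parameter containers shared by the engine and trafficking modules."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class TraffickingParams:
    """Chemokine-dependent immune entry/exit through the (implicit) vasculature.

    Influx intensities (cells/h over the whole domain) are linear in the
    mean chemokine concentration over stromal nodes:

        lambda_E = lam0_E + alpha_E * <C_dam> + beta_E * <C_dying>
        lambda_R = lam0_R + alpha_R * <C_dam>

    The damaged-cell chemokine recruits both effector and regulatory cells;
    the dying-cell "find-me" signal recruits effectors only (hence no
    C_dying term for regulatory cells). INACTIVE and PERM_INACTIVE immune
    cells exit at per-cell rate ``lam_out``; ACTIVE cells never exit.

    Defaults are the package's calibrated baseline for the default ~530
    epithelial-cell TDLU (reproducing the observed effector phase means
    0.05/0.04/0.07 and regulatory mean 0.055); recalibrate for other
    geometries with :func:`tdlusim.trafficking.calibrate`.
    """

    lam0_E: float = 3.2
    alpha_E: float = 300.0
    beta_E: float = 2270.0
    lam0_R: float = 5.1
    alpha_R: float = 300.0
    lam_out: float = 0.2

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"trafficking parameter {name} must be >= 0")


@dataclass
class SimulationParams:
    """All rate and interaction parameters of one simulation.

    Units: rates in 1/h, k_dge a probability per division, tau_lys and dt
    in hours, theta/chi dimensionless, c_act in chemokine concentration
    units. Per-step event probabilities are mapped from rates as
    1 - exp(-rate*dt), so proportional-hazard statements (killing and
    suppression scale with the number of adjacent active cells) hold
    exactly.
    """

    k_pro: float = 0.03        # baseline epithelial division rate
    k_apt: float = 0.0021      # baseline apoptosis rate (balances the measured PI)
    k_dge: float = 0.0         # P(daughter of a normal cell is damaged)
    k_kill: float = 0.10       # killing rate per adjacent active effector
    k_sup: float = 0.05        # suppression rate per adjacent active regulatory
    theta: float = 1.0         # hormone level (scales both turnover rates)
    c_act: float = 0.02        # activation threshold on the damaged-cell chemokine
    chi: float = 50.0          # chemotaxis sensitivity (softmax weight exp(chi*dC))
    m_rate: float = 10.0       # immune motility attempts per hour
    tau_lys: float = 12.0      # dying-cell debris persistence before lysis
    dt: float = 1.0            # engine time step
    trafficking: TraffickingParams = field(default_factory=TraffickingParams)
    # chemokine PDE block (passed through to ChemokineFields)
    d_dam: float = 5.0
    d_dying: float = 5.0
    lambda_dam: float = 0.5
    lambda_dying: float = 0.5
    s_dam: float = 1.0
    s_dying: float = 1.0

    def __post_init__(self):
        for name in ("k_pro", "k_apt", "k_kill", "k_sup", "m_rate", "tau_lys", "c_act", "chi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.k_dge <= 1.0:
            raise ValueError("k_dge is a probability per division and must lie in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def chemokine_kwargs(self) -> dict:
        return dict(
            d_dam=self.d_dam, d_dying=self.d_dying,
            lambda_dam=self.lambda_dam, lambda_dying=self.lambda_dying,
            s_dam=self.s_dam, s_dying=self.s_dying,
        )
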