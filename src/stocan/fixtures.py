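"""Programmatic model fixtures: the package's canonical study systems.

Four families, all generated in code (no data files):

* :func:`birth_death` — constant synthesis, first-order degradation.  The
  stationary law is Poisson, so mean and noise control vectors are exactly
  anti-parallel and orthogonal control is impossible.
* :func:`two_state_promoter` — bursty gene expression: a promoter toggling
  between inactive and active states, transcription only from the active
  state, plus translation; total promoter copies are conserved.
* :func:`linear_pathway` — an enzyme-fed three-metabolite chain.  Variant A
  (fixed enzyme, no feedback) is an open first-order network with a
  product-form Poisson stationary law; variant B adds end-product (Hill)
  inhibition of the first step; variant C replaces the fixed enzyme with
  birth-death enzyme dynamics (extrinsic noise); BC combines both.
* :func:`feedback_oscillator` — a three-species negative-feedback Langevin
  model (upstream-kinase / p53-like / Mdm2-like) whose autocorrelation shows
  damped oscillations.

Default parameter values are this package's documented choices, selected so
that every fixture has a stable steady state (and, for the oscillator, an
underdamped one); they are not tied to any particular measured system.
"""

from __future__ import annotations

import numpy as np

from .errors import SchemaError, StabilityError
from .network import Parameter, Reaction, ReactionNetwork, Species

__all__ = [
    "birth_death",
    "two_state_promoter",
    "linear_pathway",
    "feedback_oscillator",
    "get_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("birth_death", "two_state_promoter", "linear_pathway", "feedback_oscillator")


def birth_death(k_s: float = 2.0, k_d: float = 0.4) -> ReactionNetwork:
    """Synthesis-degradation process: 0 -> X at rate k_s, X -> 0 at rate k_d X.

    Stationary mean k_s/k_d, Poisson stationary law (variance equals mean,
    noise level 1/mean).
    """
    x0 = round(k_s / k_d)
    return ReactionNetwork(
        species=[Species("X", float(x0))],
        parameters=[Parameter("k_s", k_s), Parameter("k_d", k_d)],
        reactions=[
            Reaction("synthesis", {"X": +1}, "k_s"),
            Reaction("degradation", {"X": -1}, "k_d * X"),
        ],
        name="birth_death",
    )


def two_state_promoter(
    k_on: float = 0.1,
    k_off: float = 0.9,
    k_tx: float = 10.0,
    d_m: float = 1.0,
    k_tl: float = 5.0,
    d_p: float = 0.1,
    G_total: int = 1,
) -> ReactionNetwork:
    """Two-state (telegraph) promoter with transcription and translation.

    Species G_off, G_on (conserved total ``G_total``), mRNA, protein; six
    rate parameters, all with dimension 1/time.  The stationary protein mean
    is ``(k_on/(k_on+k_off)) G_total k_tx k_tl / (d_m d_p)``.
    """
    if int(G_total) != G_total or G_total < 1:
        raise SchemaError("G_total must be a positive integer")
    f_on = k_on / (k_on + k_off)
    m0 = round(f_on * G_total * k_tx / d_m)
    p0 = round(m0 * k_tl / d_p)
    return ReactionNetwork(
        species=[
            Species("G_off", float(G_total)),
            Species("G_on", 0.0),
            Species("mRNA", float(m0)),
            Species("protein", float(p0)),
        ],
        parameters=[
            Parameter("k_on", k_on),
            Parameter("k_off", k_off),
            Parameter("k_tx", k_tx),
            Parameter("d_m", d_m),
            Parameter("k_tl", k_tl),
            Parameter("d_p", d_p),
        ],
        reactions=[
            Reaction("activation", {"G_off": -1, "G_on": +1}, "k_on * G_off"),
            Reaction("deactivation", {"G_on": -1, "G_off": +1}, "k_off * G_on"),
            Reaction("transcription", {"mRNA": +1}, "k_tx * G_on"),
            Reaction("mrna_decay", {"mRNA": -1}, "d_m * mRNA"),
            Reaction("translation", {"protein": +1}, "k_tl * mRNA"),
            Reaction("protein_decay", {"protein": -1}, "d_p * protein"),
        ],
        name="two_state_promoter",
    )


#: parameters a design run on the pathway fixtures usually controls
PATHWAY_CONTROL_PARAMETERS = ["k1", "k2", "k3", "k4"]


def linear_pathway(
    variant: str = "A",
    k1: float = 1.0,
    k2: float = 2.0,
    k3: float = 1.5,
    k4: float = 1.0,
    e0: float = 10.0,
    K: float = 10.0,
    h: float = 2.0,
    a_e: float = 1.0,
    d_e: float = 0.1,
) -> ReactionNetwork:
    """Enzyme-fed linear metabolic chain E => X1 -> X2 -> X3 -> 0.

    Variants: ``A`` fixed enzyme, no feedback; ``B`` adds Hill end-product
    inhibition of the first step (``k1 E hill(X3, K, h)``); ``C`` gives the
    enzyme birth-death dynamics (synthesis ``a_e``, decay ``d_e E``) instead
    of a fixed level; ``BC`` combines both.  ``e0`` is the fixed enzyme level
    for A/B; the defaults satisfy ``a_e / d_e = e0`` so the mean enzyme level
    is the same in every variant.
    """
    variant = variant.upper()
    if variant not in ("A", "B", "C", "BC"):
        raise SchemaError(f"unknown pathway variant {variant!r}")
    feedback = "B" in variant
    dynamic_enzyme = "C" in variant

    influx_rate = "k1 * E"
    if feedback:
        influx_rate = "k1 * E * hill(X3, K, h)"

    x1 = k1 * e0 / k2
    x2 = k1 * e0 / k3
    x3 = k1 * e0 / k4
    species = [
        Species("E", e0, is_boundary=not dynamic_enzyme),
        Species("X1", round(x1)),
        Species("X2", round(x2)),
        Species("X3", round(x3)),
    ]
    params = [
        Parameter("k1", k1),
        Parameter("k2", k2),
        Parameter("k3", k3),
        Parameter("k4", k4),
    ]
    reactions = [
        Reaction("influx", {"X1": +1}, influx_rate),
        Reaction("step2", {"X1": -1, "X2": +1}, "k2 * X1"),
        Reaction("step3", {"X2": -1, "X3": +1}, "k3 * X2"),
        Reaction("efflux", {"X3": -1}, "k4 * X3"),
    ]
    if feedback:
        params += [Parameter("K", K), Parameter("h", h)]
    if dynamic_enzyme:
        params += [Parameter("a_e", a_e), Parameter("d_e", d_e)]
        reactions += [
            Reaction("enzyme_synthesis", {"E": +1}, "a_e"),
            Reaction("enzyme_decay", {"E": -1}, "d_e * E"),
        ]
    return ReactionNetwork(
        species=species,
        parameters=params,
        reactions=reactions,
        name=f"linear_pathway_{variant}",
    )


def feedback_oscillator(
    beta_a: float = 10.0,
    d_a: float = 0.1,
    k_pa: float = 0.2,
    beta_p: float = 1.0,
    d_p: float = 0.1,
    k_mp: float = 0.5,
    beta_m: float = 2.0,
    d_m: float = 0.1,
    noise_intensity: float = 1.0,
) -> ReactionNetwork:
    """Three-species negative-feedback Langevin model with damped noisy
    oscillations (upstream kinase ``A_k``, p53-like ``P``, Mdm2-like ``M``).

    Drift:  dA_k = beta_a - d_a A_k - k_pa P   (P inhibits the kinase)
            dP   = beta_p A_k - d_p P - k_mp M (M removes P)
            dM   = beta_m P - d_m M

    with additive Gaussian white noise of constant intensity per species.
    Construction fails with a "non-oscillatory fixture" error if the
    Jacobian's eigenvalues are purely real.
    """
    # deterministic steady state of the linear drift
    J = np.array(
        [[-d_a, -k_pa, 0.0], [beta_p, -d_p, -k_mp], [0.0, beta_m, -d_m]]
    )
    b = np.array([beta_a, 0.0, 0.0])
    x_star = np.linalg.solve(-J, b)
    if np.any(x_star <= 0):
        raise SchemaError(f"oscillator parameters give nonpositive steady state {x_star}")
    eig = np.linalg.eigvals(J)
    if np.all(np.abs(eig.imag) < 1e-12):
        raise StabilityError("non-oscillatory fixture: Jacobian eigenvalues are purely real")
    D = noise_intensity * np.eye(3)
    return ReactionNetwork(
        species=[
            Species("A_k", float(x_star[0])),
            Species("P", float(x_star[1])),
            Species("M", float(x_star[2])),
        ],
        parameters=[
            Parameter("beta_a", beta_a),
            Parameter("d_a", d_a),
            Parameter("k_pa", k_pa),
            Parameter("beta_p", beta_p),
            Parameter("d_p", d_p),
            Parameter("k_mp", k_mp),
            Parameter("beta_m", beta_m),
            Parameter("d_m", d_m),
        ],
        reactions=[
            Reaction("kinase_synthesis", {"A_k": +1}, "beta_a"),
            Reaction("kinase_decay", {"A_k": -1}, "d_a * A_k"),
            Reaction("kinase_inhibition", {"A_k": -1}, "k_pa * P"),
            Reaction("p_synthesis", {"P": +1}, "beta_p * A_k"),
            Reaction("p_decay", {"P": -1}, "d_p * P"),
            Reaction("p_removal", {"P": -1}, "k_mp * M"),
            Reaction("m_synthesis", {"M": +1}, "beta_m * P"),
            Reaction("m_decay", {"M": -1}, "d_m * M"),
        ],
        kind="langevin",
        diffusion=D,
        name="feedback_oscillator",
    )


def get_fixture(name: str, **overrides) -> ReactionNetwork:
    """Build a fixture by name with keyword parameter overrides."""
    builders = {
        "birth_death": birth_death,
        "two_state_promoter": two_state_promoter,
        "linear_pathway": linear_pathway,
        "feedback_oscillator": feedback_oscillator,
    }
    if name not in builders:
        raise SchemaError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return builders[name](**overrides)
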