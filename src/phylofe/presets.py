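"""Named model presets used throughout the validation studies.

All two-type presets use a Fit/Unfit phenotype pair.  The initial-type
distribution ``pi`` is uniform (the sources of these parameterizations leave
it unstated; none of the transformed-rate quantities depend on it).
"""

from __future__ import annotations

import math

from .params import BDMSParams, CSESchedule

__all__ = [
    "stick_model",
    "single_type_model",
    "fig2_two_type_model",
    "two_type_validation_model",
    "massive_subsampling_model",
    "benchmark_models",
    "PRESETS",
]


def stick_model(rho: float = 0.5, t_max: float = 1.0) -> BDMSParams:
    """Trivial process with no birth, death, mutation or serial sampling:
    the full tree is a stick, sampled at the present with probability rho."""
    return BDMSParams(
        types=["A"], pi=[1.0], lam=[[0.0]], mu=[0.0], gamma=[[0.0]],
        psi=[0.0], r=[0.0], cse=CSESchedule.present_only([rho]),
        t_max=t_max, name=f"stick(rho={rho})",
    )


def single_type_model(lam: float, mu: float = 0.0, *, psi: float = 0.0,
                      r: float = 0.0, rho: float = 1.0, t_max: float = 1.0,
                      n_max: float = math.inf) -> BDMSParams:
    """Single-type birth-death model with serial (psi, r) and present-day
    (rho) sampling."""
    return BDMSParams(
        types=["A"], pi=[1.0], lam=[[lam]], mu=[mu], gamma=[[0.0]],
        psi=[psi], r=[r], cse=CSESchedule.present_only([rho]),
        t_max=t_max, n_max=n_max,
        name=f"single(lam={lam},mu={mu},psi={psi},rho={rho})",
    )


def _two_type(lam_fit, lam_unfit, mu_fit, mu_unfit, g_fu, g_uf, rho, t_max,
              name, n_max=math.inf) -> BDMSParams:
    return BDMSParams(
        types=["Fit", "Unfit"],
        pi=[0.5, 0.5],
        lam=[[lam_fit, 0.0], [0.0, lam_unfit]],
        mu=[mu_fit, mu_unfit],
        gamma=[[0.0, g_fu], [g_uf, 0.0]],
        psi=[0.0, 0.0],
        r=[0.0, 0.0],
        cse=CSESchedule.present_only([rho, rho]),
        t_max=t_max, n_max=n_max, name=name,
    )


def fig2_two_type_model(rho: float = 0.01, t_max: float = 10.0) -> BDMSParams:
    """Fit/Unfit model used to illustrate the forward-equivalent rates:
    lam = (1.0, 0.25), mu = 0.25 for both, symmetric anagenetic mutation at
    0.5, present-day sampling probability ``rho`` (0.01 or 0.25)."""
    return _two_type(1.0, 0.25, 0.25, 0.25, 0.5, 0.5, rho, t_max,
                     name=f"fig2(rho={rho})")


def two_type_validation_model(rho: float = 0.5) -> BDMSParams:
    """Fit/Unfit model of the distribution tests: lam = (1.0, 0.25),
    mu = 0.25 for both, gamma Fit->Unfit = 0.8, Unfit->Fit = 0.1,
    present-day sampling 0.5, t_max = 20."""
    return _two_type(1.0, 0.25, 0.25, 0.25, 0.8, 0.1, rho, 20.0,
                     name=f"two-type-validation(rho={rho})")


def massive_subsampling_model(rho: float = 1e-9) -> BDMSParams:
    """Fit/Unfit model subsampled from a population in the tens of billions:
    lam = (1.0, 0.25), mu = (0.25, 0.5), gamma Fit->Unfit = 0.25,
    Unfit->Fit = 0.1, t_max = 47, present-day sampling 1e-9.

    The supercritical Fit type (net growth 0.75) against a subcritical Unfit
    sink yields a mean-field growth rate of ~0.53, hence ~4e10 extant
    lineages at the present and conditional sample sizes in the tens to
    hundreds at rho = 1e-9 -- the regime where only the forward-equivalent
    simulation is feasible.
    """
    return _two_type(1.0, 0.25, 0.25, 0.5, 0.25, 0.1, rho, 47.0,
                     name=f"massive-subsampling(rho={rho})")


def benchmark_models(rho: float):
    """The three computational-efficiency rows: single-type without death
    (lam=1, t_max=5), single-type with death (lam=mu=1, t_max=10), and the
    two-type validation model, each sampled at the present with ``rho``."""
    return {
        "single_no_death": single_type_model(1.0, 0.0, rho=rho, t_max=5.0),
        "single_with_death": single_type_model(1.0, 1.0, rho=rho, t_max=10.0),
        "two_type": two_type_validation_model(rho=rho),
    }


PRESETS = {
    "stick": stick_model,
    "single-type": single_type_model,
    "fig2": fig2_two_type_model,
    "two-type-validation": two_type_validation_model,
    "massive-subsampling": massive_subsampling_model,
}
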