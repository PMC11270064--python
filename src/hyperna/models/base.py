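"""Common interface for the ionic cell models.

Every model exposes a right-hand side ``rhs(t, y, p)`` and a pure currents
function ``currents(y, p)``, both operating on a flat state vector ``y`` and
a flat parameter vector ``p`` so the stiff integrator and the trace capture
can treat all models uniformly (and the full models can be jit-compiled).

Parameter vector layout (shared by all models)::

    p[0:4]   extracellular milieu: nao, ko, cao, clo     (mmol/L)
    p[4:10]  scaling factors: f_ICaL, f_IKr, f_IKs, f_IK1, f_INaCa, f_INaK
    p[10]    relative intracellular volume (shrinkage; capacitive area fixed)
    p[11]    stimulus current, A/F (inward negative), constant per segment
    p[12]    membrane-current mask (1 normal; 0 silences every
             transmembrane current for conservation checks)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from ..osmotic import ExtracellularMilieu, PerturbedCondition

P_NAO, P_KO, P_CAO, P_CLO = 0, 1, 2, 3
P_FCAL, P_FKR, P_FKS, P_FK1, P_FNCX, P_FNAK = 4, 5, 6, 7, 8, 9
P_VFRAC = 10
P_ISTIM = 11
P_MASK = 12
N_PARAMS = 13

#: Currents reported by every model, A/F.  Models lacking a current
#: (e.g. chloride currents in models without them) report zero.
CURRENT_NAMES: tuple[str, ...] = (
    "i_na",
    "i_nal",
    "i_to",
    "i_cal",
    "i_cana",
    "i_cak",
    "i_kr",
    "i_ks",
    "i_k1",
    "i_nak",
    "i_naca_i",
    "i_naca_ss",
    "i_nab",
    "i_kb",
    "i_cab",
    "i_pca",
    "i_clca",
    "i_clb",
)
N_CURRENTS = len(CURRENT_NAMES)


@dataclass(frozen=True)
class ModelDef:
    """A registered ionic model."""

    model_id: str
    name: str
    baseline_milieu: ExtracellularMilieu
    temperature: float
    state_names: tuple[str, ...]
    y0: np.ndarray
    rhs: Callable  # rhs(t, y, p) -> dy/dt
    currents: Callable  # currents(y, p) -> array of N_CURRENTS
    #: indices of intracellular ion-concentration states (mmol/L)
    conc_indices: Mapping[str, int] = field(default_factory=dict)
    #: optional ion_amounts(y, p) -> {"na": ..., "k": ..., "ca": ...}
    #: total intracellular amounts incl. buffers/SR (concentration x volume)
    ion_amounts: Callable | None = None
    notes: str = ""

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def initial_state(self) -> np.ndarray:
        """The model's published/default initial state (copy)."""
        return self.y0.copy()

    def pack_params(
        self,
        condition: PerturbedCondition | None = None,
        istim: float = 0.0,
        mask: float = 1.0,
    ) -> np.ndarray:
        """Flatten a perturbed condition into the shared parameter vector."""
        p = np.zeros(N_PARAMS)
        milieu = condition.milieu if condition is not None else self.baseline_milieu
        p[P_NAO] = milieu.na_e
        p[P_KO] = milieu.k_e
        p[P_CAO] = milieu.ca_e
        p[P_CLO] = milieu.cl_e
        if condition is not None:
            f = condition.factors
            p[P_FCAL:P_FNAK + 1] = (
                f.f_ICaL, f.f_IKr, f.f_IKs, f.f_IK1, f.f_INaCa, f.f_INaK,
            )
            p[P_VFRAC] = condition.volume_fraction
        else:
            p[P_FCAL:P_FNAK + 1] = 1.0
            p[P_VFRAC] = 1.0
        p[P_ISTIM] = istim
        p[P_MASK] = mask
        return p

    def validate_state(self, y: np.ndarray) -> None:
        """Raise with the offending variable named if the state is invalid."""
        bad = np.flatnonzero(~np.isfinite(y))
        if bad.size:
            raise FloatingPointError(
                f"{self.model_id}: non-finite state component "
                f"{self.state_names[bad[0]]} (index {bad[0]})"
            )


_REGISTRY: dict[str, ModelDef] = {}


def register_model(model: ModelDef) -> ModelDef:
    _REGISTRY[model.model_id] = model
    return model


def get_model(model_id: str) -> ModelDef:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def available_models() -> list[str]:
    return sorted(_REGISTRY)
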