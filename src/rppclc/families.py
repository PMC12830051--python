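"""Outcome-family specification for the provider-level summary model.

The patient-level outcomes are assumed to come from an exponential-family
GLM with canonical link.  At the provider level the only trace of the family
is the dispersion ``a(psi)`` and the cumulant-derivative sums carried in the
summary statistics, so a family spec is just the family name plus ``a(psi)``:

* ``poisson`` — transplant/death counts; ``a_psi = 1`` for the exact Poisson
  model, ``a_psi > 1`` for the quasi-Poisson extension.
* ``normal``  — continuous outcomes; ``a_psi`` is the residual variance
  ``sigma2_eps``.
* ``general`` — any other exponential family, handled through first-order
  approximations and requiring the third-cumulant sum per provider.
"""

from __future__ import annotations

from dataclasses import dataclass

_FAMILIES = ("poisson", "normal", "general")


@dataclass(frozen=True)
class FamilySpec:
    """Outcome family and dispersion ``a(psi)`` of the patient-level GLM."""

    family: str
    a_psi: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not self.a_psi > 0:
            raise ValueError(f"a_psi must be positive, got {self.a_psi}")

    @property
    def is_quasi_poisson(self) -> bool:
        """True when a Poisson family carries an overdispersion a(psi) != 1."""
        return self.family == "poisson" and self.a_psi != 1.0


POISSON = FamilySpec("poisson", 1.0)
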