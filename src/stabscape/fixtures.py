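"""Built-in model and arrangement fixtures.

Everything the test suite and the worked examples need ships with the package
as exact-rational model files: the two-ellipse arrangement, the quadratic
discriminant toy, the Holling Type II predator-prey model with a strong Allee
effect, the Levins-Culver competition-colonization model, and the
coral-bacteria symbiosis model (full, and reduced by fixing
``d = gamma_y = gamma_z = 1`` and ``beta_y = 5``).
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources

import sympy as sp

from .io import parse_arrangement_file, parse_model_file

__all__ = ["fixtures", "coral_slice", "CORAL_SLICE_VALUES", "PREDATOR_PREY_POINT"]

#: The worked-example parameter point (alpha, beta, gamma, m, K) with A free.
PREDATOR_PREY_POINT = {
    "alpha": 2,
    "beta": Fraction(3, 2),
    "gamma": 1,
    "m": Fraction(1, 2),
    "K": 1,
}

#: Slice values for the reduced coral model: coral intrinsically viable
#: (b=2 > d=1) and non-viable (b=1/2 < d=1), with the mutualist colonization
#: rate swept across the linear boundary factors beta_z - 4 and beta_z - 6.
CORAL_SLICE_VALUES = {
    "b": (sp.Integer(2), sp.Rational(1, 2)),
    "beta_z": (
        sp.Rational(5, 2),
        sp.Integer(3),
        sp.Rational(7, 2),
        sp.Rational(39, 10),
        sp.Rational(41, 10),
        sp.Rational(59, 10),
        sp.Rational(61, 10),
        sp.Integer(10),
    ),
}


def _data_path(name: str):
    return resources.files("stabscape.data").joinpath(name)


def fixtures() -> dict:
    """Registry of the shipped fixtures, loaded through the model-file reader.

    Keys: ``two_ellipses`` (arrangement), ``quadratic_discriminant``,
    ``predator_prey``, ``predator_prey_fixed`` (the worked-example point with
    only ``A`` free), ``levins_culver``, ``coral``, ``coral_reduced``, and
    ``coral_slices`` (the 16 ``(b, beta_z)`` slice parameterizations).
    """
    registry = {}
    with resources.as_file(_data_path("two_ellipses.json")) as path:
        registry["two_ellipses"] = parse_arrangement_file(path)
    for name in (
        "quadratic_discriminant",
        "predator_prey",
        "levins_culver",
        "coral",
        "coral_reduced",
    ):
        with resources.as_file(_data_path(f"{name}.json")) as path:
            registry[name] = parse_model_file(path)
    registry["predator_prey_fixed"] = registry["predator_prey"].fix(
        PREDATOR_PREY_POINT, name="predator_prey_fixed"
    )
    registry["coral_slices"] = [
        (b, bz) for b in CORAL_SLICE_VALUES["b"] for bz in CORAL_SLICE_VALUES["beta_z"]
    ]
    return registry


def coral_slice(b, beta_z):
    """The reduced coral model further restricted to one (b, beta_z) slice,
    leaving the birth benefit ``btilde`` and death detriment ``dtilde`` free."""
    reg = fixtures()
    return reg["coral_reduced"].fix(
        {"b": sp.nsimplify(b, rational=True), "beta_z": sp.nsimplify(beta_z, rational=True)},
        name=f"coral_slice_b={b}_beta_z={beta_z}",
    )
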