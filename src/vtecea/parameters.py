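"""Model parameters: point estimates, uncertainty ranges and serialization.

The model compares three thromboprophylaxis strategies for cesarean delivery
(intermittent pneumatic compression, low-molecular-weight heparin, and no
prophylaxis) from a Brazilian hospital perspective.  Every quantity the model
consumes — baseline adverse-event probabilities, per-event management costs in
2021 Brazilian Real, and the relative risks that map the no-prophylaxis
baselines onto the active strategies — is held here as an
:class:`UncertainQuantity` (a point value plus a 95% uncertainty interval and
the distribution family used by the probabilistic sensitivity analysis).

Probabilities are stored as fractions in ``[0, 1]``; published percentages are
converted once, at definition time.  Where the source literature reports no
variance, a ±10% interval around the point value is assumed.

The on-disk format is a flat ``key = value`` text file with one canonical key
per parameter (``p_dvt_baseline``, ``c_major``, ``rr_lmwh_minor`` ...) and
optional ``<key>.low`` / ``<key>.high`` sub-keys for the interval bounds.
Floats are written with full ``repr`` precision so that a write/load round
trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

__all__ = [
    "UncertainQuantity",
    "ParameterSet",
    "ParameterValidationError",
    "default_parameters",
    "load_parameters",
    "write_parameters",
    "UNCERTAIN_KEYS",
    "PARAMETER_KINDS",
]


class ParameterValidationError(ValueError):
    """Raised when a parameter set violates its invariants.

    The message names every offending key so a bad configuration file can be
    fixed in one pass.
    """


@dataclass(frozen=True)
class UncertainQuantity:
    """A point estimate with an uncertainty interval and sampling family.

    Parameters
    ----------
    value
        Point estimate (probability as a fraction, cost in 2021 R$, or a
        unitless relative risk).
    low, high
        Bounds of the uncertainty interval, read downstream as a 95% interval.
    family
        Distribution family for probabilistic sampling: ``"beta"`` for
        probabilities, ``"gamma"`` for costs, ``"lognormal"`` for relative
        risks, or ``"fixed"`` for a degenerate (point-mass) quantity.
    """

    value: float
    low: float
    high: float
    family: str = "fixed"

    def with_value(self, value: float) -> "UncertainQuantity":
        """Return a copy with a new point value (range untouched)."""
        return replace(self, value=float(value))


def _assumed_range(value: float) -> tuple[float, float]:
    # ±10% interval assumed where the source gives no variance
    return 0.9 * value, 1.1 * value


def _prob(value: float, low: float | None = None, high: float | None = None) -> UncertainQuantity:
    if low is None:
        low, high = _assumed_range(value)
    return UncertainQuantity(value, low, high, family="beta")


def _cost(value: float, low: float | None = None, high: float | None = None) -> UncertainQuantity:
    if low is None:
        low, high = _assumed_range(value)
    return UncertainQuantity(value, low, high, family="gamma")


def _rr(value: float, low: float, high: float) -> UncertainQuantity:
    return UncertainQuantity(value, low, high, family="lognormal")


# kind of each uncertain quantity; governs validation and distribution family
PARAMETER_KINDS: dict[str, str] = {
    "p_dvt_baseline": "probability",
    "p_pe_given_dvt": "probability",
    "p_minor_baseline": "probability",
    "p_major_baseline": "probability",
    "p_mortality": "probability",
    "p_hypo_baseline": "probability",
    "c_dvt": "cost",
    "c_pe": "cost",
    "c_minor": "cost",
    "c_major": "cost",
    "c_hypo": "cost",
    "c_lmwh": "cost",
    "c_ipc": "cost",
    "rr_ipc_vs_lmwh_vte": "rr",
    "rr_lmwh_dvt": "rr",
    "rr_lmwh_minor": "rr",
    "rr_lmwh_major": "rr",
    "rr_compression_hypo": "rr",
}

UNCERTAIN_KEYS: tuple[str, ...] = tuple(PARAMETER_KINDS)

_SCALAR_KEYS = ("wtp", "n_psa", "rng_seed")


@dataclass(frozen=True)
class ParameterSet:
    """The full model input set: clinical probabilities, costs, relative
    risks, and analysis settings (willingness-to-pay, PSA iteration count,
    random seed)."""

    # baseline (no-prophylaxis) event probabilities, as fractions
    p_dvt_baseline: UncertainQuantity
    p_pe_given_dvt: UncertainQuantity
    p_minor_baseline: UncertainQuantity
    p_major_baseline: UncertainQuantity
    p_mortality: UncertainQuantity
    p_hypo_baseline: UncertainQuantity
    # management / prophylaxis costs, 2021 R$
    c_dvt: UncertainQuantity
    c_pe: UncertainQuantity
    c_minor: UncertainQuantity
    c_major: UncertainQuantity
    c_hypo: UncertainQuantity
    c_lmwh: UncertainQuantity
    c_ipc: UncertainQuantity
    # relative risks
    rr_ipc_vs_lmwh_vte: UncertainQuantity
    rr_lmwh_dvt: UncertainQuantity
    rr_lmwh_minor: UncertainQuantity
    rr_lmwh_major: UncertainQuantity
    rr_compression_hypo: UncertainQuantity
    # analysis settings
    wtp: float = 15_000.0
    n_psa: int = 1_000
    rng_seed: int = 2021

    def uncertain_items(self) -> Iterator[tuple[str, UncertainQuantity]]:
        """Yield ``(canonical key, quantity)`` pairs in declaration order."""
        for key in UNCERTAIN_KEYS:
            yield key, getattr(self, key)

    def get(self, key: str) -> UncertainQuantity:
        if key not in PARAMETER_KINDS:
            raise KeyError(f"unknown parameter key: {key!r}")
        return getattr(self, key)

    def with_quantity(self, key: str, quantity: UncertainQuantity) -> "ParameterSet":
        """Return a copy with one uncertain quantity replaced."""
        if key not in PARAMETER_KINDS:
            raise KeyError(f"unknown parameter key: {key!r}")
        return replace(self, **{key: quantity})

    def with_value(self, key: str, value: float) -> "ParameterSet":
        """Return a copy with one point value replaced (range untouched)."""
        return self.with_quantity(key, self.get(key).with_value(value))

    def validation_errors(self) -> list[str]:
        """Every violated invariant, each message naming the offending key."""
        errors: list[str] = []
        for key, q in self.uncertain_items():
            kind = PARAMETER_KINDS[key]
            if kind == "probability":
                if not 0.0 <= q.value <= 1.0:
                    errors.append(f"{key}: probability {q.value} outside [0, 1]")
            elif kind == "cost":
                if q.value < 0.0:
                    errors.append(f"{key}: negative cost {q.value}")
            elif kind == "rr":
                if q.value <= 0.0:
                    errors.append(f"{key}: relative risk {q.value} must be > 0")
            if q.low < 0.0:
                errors.append(f"{key}: lower bound {q.low} is negative")
            if not q.low <= q.value <= q.high:
                errors.append(
                    f"{key}: value {q.value} outside its range [{q.low}, {q.high}]"
                )
        if self.wtp < 0:
            errors.append(f"wtp: willingness-to-pay {self.wtp} is negative")
        if self.n_psa < 1:
            errors.append(f"n_psa: iteration count {self.n_psa} must be >= 1")
        return errors

    def validate(self) -> "ParameterSet":
        errors = self.validation_errors()
        if errors:
            raise ParameterValidationError("; ".join(errors))
        return self


def default_parameters() -> ParameterSet:
    """The published baseline input set.

    Percentages are converted to fractions (0.70% DVT incidence becomes
    0.007).  Quantities published without a variance (mortality, hypotension
    incidence, minor/major bleed costs, LMWH and IPC unit costs) carry the
    assumed ±10% interval.
    """
    return ParameterSet(
        p_dvt_baseline=_prob(0.007, 0.001, 0.03),
        p_pe_given_dvt=_prob(0.20, 0.15, 0.25),
        p_minor_baseline=_prob(0.068, 0.03, 0.10),
        p_major_baseline=_prob(0.014, 0.006, 0.02),
        p_mortality=_prob(0.0026),
        p_hypo_baseline=_prob(0.6629),
        c_dvt=_cost(9_524.0, 7_486.0, 12_036.0),
        c_pe=_cost(10_618.0, 7_666.0, 13_557.0),
        c_minor=_cost(4_479.0),
        c_major=_cost(36_730.0),
        c_hypo=_cost(30.0, 20.0, 40.0),
        c_lmwh=_cost(50.0),
        c_ipc=_cost(102.0),
        rr_ipc_vs_lmwh_vte=_rr(0.87, 0.08, 9.50),
        rr_lmwh_dvt=_rr(0.33, 0.01, 7.93),
        rr_lmwh_minor=_rr(2.12, 1.15, 3.93),
        rr_lmwh_major=_rr(1.48, 0.25, 8.72),
        rr_compression_hypo=_rr(0.36, 0.22, 0.56),
    ).validate()


# ---------------------------------------------------------------------------
# serialization


def _format_float(x: float) -> str:
    return repr(float(x))


def write_parameters(params: ParameterSet, path: str | Path) -> Path:
    """Write a parameter set to the flat key=value dialect.

    Refuses to serialize an invalid set, so that every file the package emits
    is loadable.  Returns the path written.
    """
    params.validate()
    path = Path(path)
    lines = ["# vtecea parameter configuration (2021 R$; probabilities as fractions)"]
    for key, q in params.uncertain_items():
        lines.append(f"{key} = {_format_float(q.value)}")
        lines.append(f"{key}.low = {_format_float(q.low)}")
        lines.append(f"{key}.high = {_format_float(q.high)}")
    lines.append(f"wtp = {_format_float(params.wtp)}")
    lines.append(f"n_psa = {params.n_psa}")
    lines.append(f"rng_seed = {params.rng_seed}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_config(text: str, source: str) -> dict[str, str]:
    entries: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterValidationError(
                f"{source}:{lineno}: expected 'key = value', got {raw!r}"
            )
        key, value = (part.strip() for part in line.split("=", 1))
        entries[key] = value
    return entries


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter set, falling back to defaults for missing keys.

    An empty file therefore yields :func:`default_parameters` exactly.  All
    invariants are checked after overrides are applied; violations raise
    :class:`ParameterValidationError` naming every offending key.
    """
    path = Path(path)
    entries = _parse_config(path.read_text(), str(path))

    params = default_parameters()
    known = set(UNCERTAIN_KEYS) | set(_SCALAR_KEYS)
    updates: dict[str, UncertainQuantity] = {}
    scalars: dict[str, float | int] = {}
    for key, raw in entries.items():
        base_key, _, attr = key.partition(".")
        if base_key not in known:
            raise ParameterValidationError(f"unknown parameter key: {base_key!r}")
        if base_key in _SCALAR_KEYS:
            if attr:
                raise ParameterValidationError(f"scalar key {base_key!r} has no field {attr!r}")
            scalars[base_key] = float(raw) if base_key == "wtp" else int(raw)
            continue
        if attr not in ("", "low", "high"):
            raise ParameterValidationError(f"unknown sub-key {attr!r} for {base_key!r}")
        q = updates.get(base_key, params.get(base_key))
        try:
            value = float(raw)
        except ValueError as exc:
            raise ParameterValidationError(f"{key}: not a number: {raw!r}") from exc
        if attr == "":
            # a bare value override widens the stored range if needed, so a
            # single-key override stays loadable without restating the bounds
            q = replace(q, value=value, low=min(q.low, value), high=max(q.high, value))
        elif attr == "low":
            q = replace(q, low=value)
        else:
            q = replace(q, high=value)
        updates[base_key] = q

    for key, q in updates.items():
        params = params.with_quantity(key, q)
    if scalars:
        params = replace(params, **scalars)
    return params.validate()


def parameters_equal(a: ParameterSet, b: ParameterSet) -> bool:
    """Field-for-field equality at full precision."""
    return dataclasses.asdict(a) == dataclasses.asdict(b)
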