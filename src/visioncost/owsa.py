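"""One-way deterministic sensitivity analysis (tornado).

Every scalar numeric leaf of the parameter tree (prevalences, unit
costs, probabilities, frequencies, days, wages, rates) is perturbed
multiplicatively one at a time — by default ±20% — and the grand total
recomputed from scratch each time.  Entries are ranked by output span
|high − low| to give the tornado ordering.  Fraction-valued leaves that
would exceed 1 after perturbation are clamped to 1 and flagged rather
than rejected.

Parameter paths are dotted, with dict keys and list indices inline,
e.g. ``population.retinopathy_prevalence``,
``unit_costs.oct.cost_sar`` or ``protocols.M2.0.multiplicity``.
A config may exclude paths from the analysis via ``owsa_exclude``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
from pydantic import ValidationError

from .config import ModelParameters
from .results import run_model

#: Top-level keys that are not model inputs.
_SKIP_KEYS = frozenset({"coi_schema", "annotations", "owsa_exclude"})


def _walk(node, prefix: str, out: list[str]) -> None:
    if isinstance(node, dict):
        for key, child in node.items():
            _walk(child, f"{prefix}{key}." if prefix or key else f"{key}.", out)
    elif isinstance(node, list):
        for i, child in enumerate(node):
            _walk(child, f"{prefix}{i}.", out)
    elif isinstance(node, bool) or node is None:
        return
    elif isinstance(node, (int, float)):
        out.append(prefix[:-1])


def enumerate_parameters(params: ModelParameters) -> list[str]:
    """Deterministic sorted list of every perturbable scalar leaf."""
    payload = params.model_dump()
    out: list[str] = []
    for key, node in payload.items():
        if key in _SKIP_KEYS:
            continue
        _walk(node, f"{key}.", out)
    return sorted(out)


def _get(payload: dict, path: str):
    node = payload
    for part in path.split("."):
        if isinstance(node, list):
            node = node[int(part)]
        else:
            node = node[part]
    return node


def _set(payload: dict, path: str, value) -> None:
    parts = path.split(".")
    node = payload
    for part in parts[:-1]:
        node = node[int(part)] if isinstance(node, list) else node[part]
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        node[last] = value


def perturb(
    params: ModelParameters, path: str, multiplier: float
) -> tuple[ModelParameters, bool]:
    """A copy of ``params`` with the leaf at ``path`` multiplied.

    Returns ``(new_params, clamped)``; ``clamped`` is True when a
    fraction-valued leaf was capped at 1.  The original is untouched.
    """
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    payload = copy.deepcopy(params.model_dump())
    try:
        value = _get(payload, path)
    except (KeyError, IndexError, ValueError) as exc:
        raise KeyError(f"unknown parameter path {path!r}") from exc
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise KeyError(f"parameter path {path!r} is not a scalar numeric leaf")
    _set(payload, path, value * multiplier)
    try:
        return ModelParameters.model_validate(payload), False
    except ValidationError as exc:
        errors = exc.errors()
        # A fraction pushed past its [0, 1] bound is clamped, not an error.
        if value * multiplier > 1.0 and all(
            err["type"] == "less_than_equal" for err in errors
        ):
            _set(payload, path, 1.0)
            return ModelParameters.model_validate(payload), True
        # Perturbing the retinopathy/maculopathy/combined prevalences can
        # break the overlap invariant; the combined prevalence is clamped
        # down to their sum (correction factor capped at 1) and flagged.
        if all("correction factor" in str(err.get("msg", "")) for err in errors):
            pop = payload["population"]
            pop["combined_prevalence"] = min(
                pop["combined_prevalence"],
                pop["retinopathy_prevalence"] + pop["maculopathy_prevalence"],
            )
            return ModelParameters.model_validate(payload), True
        raise


@dataclass(frozen=True)
class OwsaEntry:
    """One parameter's tornado bar."""

    parameter: str
    baseline_output: float
    low_output: float
    high_output: float
    clamped: bool = False

    @property
    def span(self) -> float:
        return abs(self.high_output - self.low_output)


def one_way_sensitivity(
    params: ModelParameters,
    fraction: float = 0.2,
    paths: Sequence[str] | None = None,
    output: Callable[[ModelParameters], float] | None = None,
) -> list[OwsaEntry]:
    """Tornado analysis of the grand total (SAR) over all scalar inputs.

    ``paths`` restricts the analysis; otherwise every enumerated leaf is
    used minus the config's ``owsa_exclude`` list.  Entries are sorted by
    span descending, ties broken by parameter path ascending.
    """
    if fraction < 0:
        raise ValueError(f"perturbation fraction must be >= 0, got {fraction}")
    metric = output or (lambda p: run_model(p).total_sar)
    if paths is None:
        excluded = set(params.owsa_exclude)
        paths = [p for p in enumerate_parameters(params) if p not in excluded]

    baseline = metric(params)
    entries: list[OwsaEntry] = []
    for path in paths:
        low_params, clamped_low = perturb(params, path, 1.0 - fraction)
        high_params, clamped_high = perturb(params, path, 1.0 + fraction)
        entries.append(
            OwsaEntry(
                parameter=path,
                baseline_output=baseline,
                low_output=metric(low_params),
                high_output=metric(high_params),
                clamped=clamped_low or clamped_high,
            )
        )
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


def tornado_table(entries: Iterable[OwsaEntry]) -> pd.DataFrame:
    """Tornado entries as a table ready for TSV export."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_output": e.low_output,
                "high_output": e.high_output,
                "span": e.span,
                "clamped": e.clamped,
            }
            for e in entries
        ]
    )
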