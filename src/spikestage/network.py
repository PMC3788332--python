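"""Network description documents: parsing, validation, expansion, generation.

A network is described by a JSON document with neuron groups, connection
specifications, explicit synapses, stimuli and reports.  Parsing fully
validates the document, materialises every default, and deterministically
expands probabilistic connection specs using the document seed, yielding a
flat :class:`Network` whose element IDs ("network IDs") are stable
regardless of how the simulation is later partitioned across devices.

Document shape (all sections but ``groups`` optional)::

    {
      "seed": 42,
      "groups":      [{"name", "model": "izh"|"lif", "count",
                       "params" | "pattern": "RS"|"FS"|"B"}],
      "connections": [{"pre", "post", "probability",
                       "weight": x | {"uniform": [lo, hi]},
                       "delay":  d | {"uniform_int": [lo, hi]},
                       "template": "default" | [amplitudes]}],
      "synapses":    [{"pre": [group, idx], "post": [group, idx],
                       "weight", "delay", "template"}],
      "stimuli":     [{"group", "indices"?, "kind": "current"|"clamp",
                       "amplitude", "start", "end", "probability"?}],
      "reports":     [{"name", "group", "indices"?,
                       "value": "voltage"|"spike"|"input_current"|
                                "synaptic_current"|"spike_count",
                       "cadence": 1, "sink": "file.csv"|"memory"}]
    }

The synthetic benchmark generator emits documents of the same shape with
a 100:1 synapse:neuron ratio and uniform integer delays by default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import neurons as nm
from .rng import child_rng
from .scopes import ConfigurationError
from .synapses import StimulusSpec, default_psg_template

__all__ = [
    "Network",
    "GeneratorSpec",
    "parse_network",
    "parse_network_file",
    "generate_network",
    "ReportSpec",
]

VALUE_KINDS = (
    "voltage",
    "spike",
    "input_current",
    "synaptic_current",
    "spike_count",
)


@dataclass(frozen=True)
class ReportSpec:
    """What to extract, from which elements, how often, and where to."""

    name: str
    element_ids: tuple[int, ...]
    value: str
    cadence: int = 1
    sink: str = "memory"

    def __post_init__(self) -> None:
        if self.value not in VALUE_KINDS:
            raise ConfigurationError(
                f"report {self.name!r}: unknown value kind {self.value!r}"
            )
        if self.cadence < 1:
            raise ConfigurationError(f"report {self.name!r}: cadence must be >= 1")


@dataclass
class Element:
    """One neuron-like simulated element (a cell or one of its compartments)."""

    network_id: int
    model: str  # "izh" | "lif"
    params: Any
    cell_id: int
    compartment: int = 0
    couplings: tuple[tuple[int, float], ...] = ()  # (sibling network ID, g)


@dataclass
class Network:
    """Flat, validated, fully-expanded simulation description."""

    elements: list[Element]
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_weight: np.ndarray
    syn_delay: np.ndarray
    syn_template_id: np.ndarray
    templates: list[np.ndarray]
    stimuli: list[StimulusSpec]
    reports: list[ReportSpec]
    seed: int
    groups: dict[str, list[int]]  # group name -> soma network IDs
    document: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_synapses(self) -> int:
        return int(self.syn_pre.size)

    def serialize(self) -> str:
        """Canonical JSON text; parsing it again reproduces this network."""
        return json.dumps(self.document, indent=2, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.document, sort_keys=True).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# parsing helpers
# --------------------------------------------------------------------------


def _err(path: str, msg: str) -> ConfigurationError:
    return ConfigurationError(f"{path}: {msg}")


def _require(doc: dict, key: str, path: str) -> Any:
    if key not in doc:
        raise _err(path, f"missing required field {key!r}")
    return doc[key]


def _izh_params(raw: dict, path: str) -> nm.IzhParams:
    if "pattern" in raw:
        pat = raw["pattern"]
        if pat not in nm.CANONICAL_IZH:
            raise _err(path, f"unknown pattern {pat!r}")
        return nm.CANONICAL_IZH[pat]
    try:
        return nm.IzhParams(**raw.get("params", {}))
    except (TypeError, ValueError) as exc:
        raise _err(path, str(exc)) from exc


def _lif_params(raw: dict, path: str) -> nm.LIFCompartmentParams:
    if "pattern" in raw:
        pat = raw["pattern"]
        if pat not in nm.CANONICAL_LIF:
            raise _err(path, f"unknown pattern {pat!r}")
        return nm.CANONICAL_LIF[pat]
    p = dict(raw.get("params", {}))
    try:
        if "spike_template" in p:
            p["spike_template"] = tuple(float(x) for x in p["spike_template"])
        if "kv_channels" in p:
            p["kv_channels"] = tuple(
                nm.VoltageGatedChannelParams(**c) for c in p["kv_channels"]
            )
        if "kca_channels" in p:
            p["kca_channels"] = tuple(
                nm.CalciumActivatedChannelParams(**c) for c in p["kca_channels"]
            )
        return nm.LIFCompartmentParams(**p)
    except (TypeError, ValueError) as exc:
        raise _err(path, str(exc)) from exc


def _scalar_or_uniform(raw: Any, rng: np.random.Generator, n: int, path: str) -> np.ndarray:
    if isinstance(raw, (int, float)):
        return np.full(n, float(raw))
    if isinstance(raw, dict) and "uniform" in raw:
        lo, hi = raw["uniform"]
        return rng.uniform(lo, hi, size=n)
    raise _err(path, f"expected number or {{'uniform': [lo, hi]}}, got {raw!r}")


def _delay_spec(raw: Any, rng: np.random.Generator, n: int, path: str) -> np.ndarray:
    if isinstance(raw, int):
        d = np.full(n, raw, dtype=np.int64)
    elif isinstance(raw, dict) and "uniform_int" in raw:
        lo, hi = raw["uniform_int"]
        d = rng.integers(lo, hi + 1, size=n)
    else:
        raise _err(path, f"expected integer or {{'uniform_int': [lo, hi]}}, got {raw!r}")
    if d.size and d.min() < 1:
        raise _err(path, "synaptic delays must be >= 1 step")
    return d


# --------------------------------------------------------------------------
# parse_network
# --------------------------------------------------------------------------


def parse_network(text: str) -> Network:
    """Parse and validate a JSON network document into a flat network.

    All defaults are materialised and probabilistic connection specs are
    expanded with streams derived from the document seed, so two parses of
    the same text produce identical synapse lists.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"document is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError("document root must be a JSON object")

    seed = int(doc.get("seed", 0))
    raw_groups = _require(doc, "groups", "$")
    if not raw_groups:
        raise ConfigurationError("$.groups: at least one neuron group required")

    elements: list[Element] = []
    groups: dict[str, list[int]] = {}
    cell_counter = 0
    for gi, g in enumerate(raw_groups):
        path = f"$.groups[{gi}]"
        name = _require(g, "name", path)
        if name in groups:
            raise _err(path, f"duplicate group name {name!r}")
        model = _require(g, "model", path)
        count = int(_require(g, "count", path))
        if count < 1:
            raise _err(path, f"count must be >= 1, got {count}")
        somas: list[int] = []
        if model == "izh":
            params = _izh_params(g, path)
            for _ in range(count):
                nid = len(elements)
                elements.append(Element(nid, "izh", params, cell_counter))
                somas.append(nid)
                cell_counter += 1
        elif model == "lif":
            comps_raw = g.get("compartments")
            if comps_raw:
                comp_params = [
                    _lif_params({"params": c.get("params", {})}, f"{path}.compartments[{k}]")
                    for k, c in enumerate(comps_raw)
                ]
                raw_coupl = [c.get("couplings", []) for c in comps_raw]
            else:
                comp_params = [_lif_params(g, path)]
                raw_coupl = [[]]
            for _ in range(count):
                base = len(elements)
                for k, cp in enumerate(comp_params):
                    nid = len(elements)
                    coup = tuple(
                        (base + int(other), float(gc)) for other, gc in raw_coupl[k]
                    )
                    for other, _gc in coup:
                        if not base <= other < base + len(comp_params):
                            raise _err(
                                path, "couplings must reference sibling compartments"
                            )
                    elements.append(
                        Element(nid, "lif", cp, cell_counter, compartment=k, couplings=coup)
                    )
                somas.append(base)
                cell_counter += 1
        else:
            raise _err(path, f"unknown model {model!r} (expected 'izh' or 'lif')")
        groups[name] = somas

    # templates: index 0 is the default psg waveform
    templates: list[np.ndarray] = [default_psg_template()]

    def template_id(raw: Any, path: str) -> int:
        if raw in (None, "default"):
            return 0
        if isinstance(raw, list):
            arr = np.asarray(raw, dtype=np.float64)
            if arr.size == 0:
                raise _err(path, "psg template must be non-empty")
            if not np.isclose(np.abs(arr).max(), 1.0):
                raise _err(path, "psg template must be peak-normalised (max |amp| = 1)")
            for i, t in enumerate(templates):
                if t.shape == arr.shape and np.array_equal(t, arr):
                    return i
            templates.append(arr)
            return len(templates) - 1
        raise _err(path, f"expected 'default' or an amplitude list, got {raw!r}")

    def resolve_group(name: str, path: str) -> list[int]:
        if name not in groups:
            raise _err(path, f"reference to unknown group {name!r}")
        return groups[name]

    pre_l: list[np.ndarray] = []
    post_l: list[np.ndarray] = []
    w_l: list[np.ndarray] = []
    d_l: list[np.ndarray] = []
    tid_l: list[np.ndarray] = []

    for ci, c in enumerate(doc.get("connections", [])):
        path = f"$.connections[{ci}]"
        pre_ids = np.asarray(resolve_group(_require(c, "pre", path), path))
        post_ids = np.asarray(resolve_group(_require(c, "post", path), path))
        prob = float(c.get("probability", 1.0))
        if not 0.0 <= prob <= 1.0:
            raise _err(path, f"probability must be in [0, 1], got {prob}")
        rng = child_rng(seed, f"connections/{ci}")
        mask = rng.random((pre_ids.size, post_ids.size)) < prob
        pi, qi = np.nonzero(mask)
        n = pi.size
        pre_l.append(pre_ids[pi])
        post_l.append(post_ids[qi])
        w_l.append(_scalar_or_uniform(_require(c, "weight", path), rng, n, path))
        d_l.append(_delay_spec(_require(c, "delay", path), rng, n, path))
        tid_l.append(np.full(n, template_id(c.get("template"), path), dtype=np.int64))

    for si, s in enumerate(doc.get("synapses", [])):
        path = f"$.synapses[{si}]"

        def one(endpoint: Any, p: str) -> int:
            gname, idx = endpoint
            ids = resolve_group(gname, p)
            if not 0 <= int(idx) < len(ids):
                raise _err(p, f"index {idx} out of range for group {gname!r}")
            return ids[int(idx)]

        pre_l.append(np.array([one(_require(s, "pre", path), path)]))
        post_l.append(np.array([one(_require(s, "post", path), path)]))
        w_l.append(np.array([float(_require(s, "weight", path))]))
        d_l.append(_delay_spec(int(_require(s, "delay", path)), None, 1, path))
        tid_l.append(np.array([template_id(s.get("template"), path)], dtype=np.int64))

    if pre_l:
        syn_pre = np.concatenate(pre_l).astype(np.int64)
        syn_post = np.concatenate(post_l).astype(np.int64)
        syn_weight = np.concatenate(w_l).astype(np.float64)
        syn_delay = np.concatenate(d_l).astype(np.int64)
        syn_tid = np.concatenate(tid_l).astype(np.int64)
    else:
        syn_pre = np.empty(0, dtype=np.int64)
        syn_post = np.empty(0, dtype=np.int64)
        syn_weight = np.empty(0, dtype=np.float64)
        syn_delay = np.empty(0, dtype=np.int64)
        syn_tid = np.empty(0, dtype=np.int64)

    stimuli: list[StimulusSpec] = []
    clamp_claims: dict[int, list[tuple[int, int]]] = {}
    for si, s in enumerate(doc.get("stimuli", [])):
        path = f"$.stimuli[{si}]"
        ids = resolve_group(_require(s, "group", path), path)
        indices = s.get("indices")
        if indices is None:
            targets = ids
        else:
            for idx in indices:
                if not 0 <= int(idx) < len(ids):
                    raise _err(path, f"index {idx} out of range")
            targets = [ids[int(i)] for i in indices]
        kind = _require(s, "kind", path)
        spec_kw = dict(
            kind=kind,
            amplitude=float(_require(s, "amplitude", path)),
            start_step=int(s.get("start", 0)),
            end_step=int(_require(s, "end", path)),
            probability=s.get("probability"),
        )
        for t in targets:
            try:
                spec = StimulusSpec(target=t, **spec_kw)
            except ConfigurationError as exc:
                raise _err(path, str(exc)) from exc
            if kind == "clamp":
                window = (spec.start_step, spec.end_step)
                for w0, w1 in clamp_claims.get(t, []):
                    if w0 < window[1] and window[0] < w1:
                        raise _err(
                            path,
                            f"two voltage clamps overlap on neuron {t} "
                            f"(steps [{max(w0, window[0])}, {min(w1, window[1])}))",
                        )
                clamp_claims.setdefault(t, []).append(window)
            stimuli.append(spec)

    reports: list[ReportSpec] = []
    for ri, r in enumerate(doc.get("reports", [])):
        path = f"$.reports[{ri}]"
        ids = resolve_group(_require(r, "group", path), path)
        indices = r.get("indices")
        chosen = (
            ids if indices is None else [ids[int(i)] for i in indices]
        )
        try:
            reports.append(
                ReportSpec(
                    name=_require(r, "name", path),
                    element_ids=tuple(chosen),
                    value=_require(r, "value", path),
                    cadence=int(r.get("cadence", 1)),
                    sink=r.get("sink", "memory"),
                )
            )
        except ConfigurationError as exc:
            raise _err(path, str(exc)) from exc

    if "generator" in doc:
        gen = doc["generator"]
        gpre, gpost, gw, gd = _sample_benchmark_synapses(
            n_total=len(elements),
            n_inhibitory=int(gen["n_inhibitory"]),
            n_synapses=int(gen["n_synapses"]),
            delay_range=tuple(gen["delay_range"]),
            weight_range=tuple(gen["weight_range"]),
            inhibitory_weight_range=tuple(gen["inhibitory_weight_range"]),
            seed=seed,
        )
        syn_pre = np.concatenate([syn_pre, gpre])
        syn_post = np.concatenate([syn_post, gpost])
        syn_weight = np.concatenate([syn_weight, gw])
        syn_delay = np.concatenate([syn_delay, gd])
        syn_tid = np.concatenate(
            [syn_tid, np.zeros(gpre.size, dtype=np.int64)]
        )

    net = Network(
        elements=elements,
        syn_pre=syn_pre,
        syn_post=syn_post,
        syn_weight=syn_weight,
        syn_delay=syn_delay,
        syn_template_id=syn_tid,
        templates=templates,
        stimuli=stimuli,
        reports=reports,
        seed=seed,
        groups=groups,
        document=doc,
    )
    return net


def parse_network_file(path: str) -> Network:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_network(fh.read())


# --------------------------------------------------------------------------
# synthetic benchmark generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions for the synthetic benchmark network.

    Defaults reproduce the benchmark regime: a 100:1 synapse:neuron ratio
    with integer delays uniform in [1, 20] steps.  Pre/post pairs are drawn
    uniformly with replacement (self-loops and multi-synapses allowed).
    Weights follow the classic random-network split: the last
    ``inhibitory_fraction`` of each group's neurons project negative
    weights, the rest positive; the default noisy per-neuron current
    stimulus keeps generated networks active at cortical-like rates.
    """

    n_neurons: int = 1000
    synapse_ratio: float = 100.0
    delay_range: tuple[int, int] = (1, 20)
    weight_range: tuple[float, float] = (0.0, 0.5)
    inhibitory_fraction: float = 0.2
    inhibitory_weight_range: tuple[float, float] = (-1.0, 0.0)
    model_mix: tuple[tuple[str, float], ...] = (("izh", 1.0),)
    stimulus_probability: float = 0.05
    stimulus_amplitude: float = 15.0
    duration_steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synapse_ratio < 0:
            raise ConfigurationError("synapse_ratio must be >= 0")
        if self.delay_range[0] < 1 or self.delay_range[1] < self.delay_range[0]:
            raise ConfigurationError("delay range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ConfigurationError("inhibitory_fraction must be in [0, 1]")
        total = sum(frac for _, frac in self.model_mix)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("model mix fractions must sum to 1")


def _sample_benchmark_synapses(
    n_total: int,
    n_inhibitory: int,
    n_synapses: int,
    delay_range: tuple[int, int],
    weight_range: tuple[float, float],
    inhibitory_weight_range: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Uniform pre/post pair sampling for the benchmark generator.

    Self-loops and duplicate pairs are allowed (multi-synapses are
    biologically meaningful and sampling with replacement is O(m) at any
    ratio).  Neurons with the highest IDs form the inhibitory population:
    their efferents get weights from the inhibitory range.
    """
    rng = child_rng(seed, "generator")
    pre = rng.integers(0, n_total, size=n_synapses).astype(np.int64)
    post = rng.integers(0, n_total, size=n_synapses).astype(np.int64)
    delays = rng.integers(
        delay_range[0], delay_range[1] + 1, size=n_synapses
    ).astype(np.int64)
    inh = pre >= (n_total - n_inhibitory)
    w_exc = rng.uniform(*weight_range, size=n_synapses)
    w_inh = rng.uniform(*inhibitory_weight_range, size=n_synapses)
    weights = np.where(inh, w_inh, w_exc).astype(np.float64)
    return pre, post, weights, delays


def generate_network(spec: GeneratorSpec) -> Network:
    """Generate a random benchmark network honouring the synapse ratio exactly.

    The synapse count is exactly ``round(n_neurons * synapse_ratio)``; all
    draws derive from ``spec.seed``, so the same spec always yields the
    identical network.  The emitted document carries a ``generator``
    section, so serialising and re-parsing reproduces the same synapses.

    Excitatory neurons (regular-spiking parameters) come first, split
    across the model mix; the last ``inhibitory_fraction`` of neurons form
    a fast-spiking inhibitory group.
    """
    n = spec.n_neurons
    if n < 1:
        raise ConfigurationError("n_neurons must be >= 1")
    m = int(round(n * spec.synapse_ratio))

    n_inh = int(round(spec.inhibitory_fraction * n))
    n_exc = n - n_inh
    groups: list[dict] = []
    assigned = 0
    mix = [(model, frac) for model, frac in spec.model_mix]
    for i, (model, frac) in enumerate(mix):
        c = n_exc - assigned if i == len(mix) - 1 else int(round(frac * n_exc))
        if c > 0:
            groups.append(
                {"name": f"exc_{model}{i}", "model": model, "count": c,
                 "pattern": "RS"}
            )
        assigned += c
    if n_inh > 0:
        groups.append(
            {"name": "inh_izh", "model": "izh", "count": n_inh, "pattern": "FS"}
        )
    if not groups:
        raise ConfigurationError("generator produced no neuron groups")

    doc = {
        "seed": int(spec.seed),
        "groups": groups,
        "stimuli": [
            {
                "group": g["name"],
                "kind": "current",
                "amplitude": spec.stimulus_amplitude,
                "start": 0,
                "end": int(spec.duration_steps),
                "probability": spec.stimulus_probability,
            }
            for g in groups
        ],
        "reports": [
            {
                "name": f"raster_{g['name']}",
                "group": g["name"],
                "value": "spike",
                "cadence": 1,
                "sink": "memory",
            }
            for g in groups
        ],
        "generator": {
            "n_inhibitory": n_inh,
            "n_synapses": m,
            "delay_range": list(spec.delay_range),
            "weight_range": list(spec.weight_range),
            "inhibitory_weight_range": list(spec.inhibitory_weight_range),
        },
    }
    return parse_network(json.dumps(doc))
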