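"""Process/activity framework.

A process is an ordered sequence of activities executed strictly in
sequence on an accumulated list of named data nodes.  Activities never
mutate their inputs; each produces new output nodes.  Failure is
fail-fast: the first failing activity yields an :class:`ErrorVector` and
no outputs are registered.  Definitions are parsed from an XML document
(moduleList / process / activity / inputList / outputList) and validated
against the plugin registry at parse time.
"""

from __future__ import annotations

import importlib.resources
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import classify_stockwell, classify_svm, detect, features, preprocess
from .signal_model import EventList, Recording, SignalModelError

__all__ = [
    "DataNode",
    "ActivitySpec",
    "ProcessDefinition",
    "ParameterSet",
    "ErrorVector",
    "ProcessResult",
    "ActivityRegistry",
    "default_registry",
    "register_activity",
    "parse_process_definition",
    "serialize_process_definitions",
    "load_bundled_definitions",
    "load_default_parameters",
    "run_process",
]

PRIMARY_INPUT = "input"


class PipelineError(SignalModelError):
    pass


@dataclass
class DataNode:
    """A named payload moving through a process (recording/events/features)."""

    name: str
    kind: str  # "recording" | "events" | "features"
    payload: object


@dataclass
class ActivitySpec:
    activity_name: str
    module_ref: str
    input_list: list[str] = field(default_factory=list)


@dataclass
class ProcessDefinition:
    name: str
    reference: str = ""
    activities: list[ActivitySpec] = field(default_factory=list)
    output_list: list[str] = field(default_factory=list)

    def validate(self, registry: "ActivityRegistry") -> None:
        if not self.activities:
            raise PipelineError(f"process {self.name!r} has no activities")
        known = {PRIMARY_INPUT}
        for act in self.activities:
            if not registry.has(act.module_ref):
                raise PipelineError(
                    f"process {self.name!r} / activity {act.activity_name!r}: "
                    f"unknown module {act.module_ref!r}"
                )
            for ref in act.input_list:
                if ref not in known:
                    raise PipelineError(
                        f"process {self.name!r} / activity {act.activity_name!r}: "
                        f"input {ref!r} does not resolve to the primary input "
                        f"or an earlier activity"
                    )
            known.add(act.activity_name)
        for ref in self.output_list:
            if ref not in known:
                raise PipelineError(
                    f"process {self.name!r}: output {ref!r} not produced"
                )


@dataclass
class ParameterSet:
    """Per-activity named parameter values, serializable as JSON."""

    set_id: str = "default"
    per_activity: dict = field(default_factory=dict)
    seed: int = 0

    def activity(self, name: str) -> dict:
        return dict(self.per_activity.get(name, {}))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"set_id": self.set_id, "seed": self.seed,
                 "per_activity": self.per_activity},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            set_id=doc.get("set_id", "default"),
            per_activity=doc.get("per_activity", {}),
            seed=doc.get("seed", 0),
        )


@dataclass
class ErrorVector:
    activity_name: str
    stage: int
    message: str

    def __bool__(self) -> bool:  # truthy: an error happened
        return True


@dataclass
class ProcessResult:
    outputs: dict[str, DataNode]
    all_nodes: dict[str, DataNode]
    error: ErrorVector | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


# ---------------------------------------------------------------------------
# registry

ActivityFn = Callable[[list[DataNode], dict], list[DataNode]]


class ActivityRegistry:
    def __init__(self) -> None:
        self._activities: dict[str, tuple[ActivityFn, dict]] = {}

    def register(self, identifier: str, fn: ActivityFn, schema: dict | None = None) -> None:
        if identifier in self._activities:
            raise PipelineError(f"activity {identifier!r} already registered")
        self._activities[identifier] = (fn, schema or {})

    def has(self, identifier: str) -> bool:
        return identifier in self._activities

    def get(self, identifier: str) -> tuple[ActivityFn, dict]:
        try:
            return self._activities[identifier]
        except KeyError:
            raise PipelineError(f"unknown activity {identifier!r}") from None

    def names(self) -> list[str]:
        return sorted(self._activities)


# ---------------------------------------------------------------------------
# built-in activities


def _require(nodes: list[DataNode], kind: str) -> DataNode:
    for node in nodes:
        if node.kind == kind:
            return node
    raise PipelineError(f"activity requires an input node of kind {kind!r}")


def _act_fir_filter(nodes: list[DataNode], params: dict) -> list[DataNode]:
    rec: Recording = _require(nodes, "recording").payload
    rate = rec.epochs[0].channels[0].rate
    kernel = preprocess.design_fir(
        params.get("low_hz"),
        params.get("high_hz"),
        rate,
        n_taps=int(params.get("n_taps", preprocess.DEFAULT_TAPS)),
        self_convolve=bool(params.get("self_convolve", False)),
    )
    return [DataNode("filtered", "recording", preprocess.apply_fir(rec, kernel))]


def _act_emd_filter(nodes: list[DataNode], params: dict) -> list[DataNode]:
    rec: Recording = _require(nodes, "recording").payload
    out = preprocess.emd_highpass(
        rec,
        first_imf=int(params.get("first_imf", 1)),
        n_imfs=int(params.get("n_imfs", 1)),
        epsilon=float(params.get("epsilon", preprocess.DEFAULT_EPSILON)),
    )
    return [DataNode("emd_filtered", "recording", out)]


def _act_rms_detector(nodes: list[DataNode], params: dict) -> list[DataNode]:
    rec: Recording = _require(nodes, "recording").payload
    p = detect.RmsParams(**{k: params[k] for k in params if k in detect.RmsParams.__dataclass_fields__})
    events = detect.detect_recording(rec, "rms", p)
    return [DataNode("eoi", "events", events)]


def _act_hilbert_detector(nodes: list[DataNode], params: dict) -> list[DataNode]:
    rec: Recording = _require(nodes, "recording").payload
    p = detect.HilbertParams(**{k: params[k] for k in params if k in detect.HilbertParams.__dataclass_fields__})
    events = detect.detect_recording(rec, "hilbert", p)
    return [DataNode("eoi", "events", events)]


def _act_stockwell_classifier(nodes: list[DataNode], params: dict) -> list[DataNode]:
    events: EventList = _require(nodes, "events").payload
    rec: Recording = _require(nodes, "recording").payload
    p = classify_stockwell.StockwellParams(
        **{k: params[k] for k in params
           if k in classify_stockwell.StockwellParams.__dataclass_fields__}
    )
    labeled = classify_stockwell.classify_events_stockwell(events, rec, p)
    return [DataNode("classified", "events", labeled)]


def _act_time_features(nodes: list[DataNode], params: dict) -> list[DataNode]:
    events: EventList = _require(nodes, "events").payload
    rec: Recording = _require(nodes, "recording").payload
    selection = tuple(params.get("selection", features.TIME_FEATURE_NAMES))
    table = features.extract_time_features(
        events, rec, selection, table_name=params.get("table_name", "time")
    )
    return [DataNode("time_features", "features", table)]


def _act_frequency_features(nodes: list[DataNode], params: dict) -> list[DataNode]:
    events: EventList = _require(nodes, "events").payload
    rec: Recording = _require(nodes, "recording").payload
    table = features.extract_spectral_features(
        events,
        rec,
        f_lo=float(params.get("f_lo", 0.0)),
        f_hi=float(params.get("f_hi", 850.0)),
        bin_hz=float(params.get("bin_hz", 10.0)),
        normalize=bool(params.get("normalize", True)),
        table_name=params.get("table_name", "spec"),
    )
    return [DataNode("frequency_features", "features", table)]


def _act_svm_classifier(nodes: list[DataNode], params: dict) -> list[DataNode]:
    model_file = params.get("model_file")
    if not model_file:
        raise PipelineError("svm_classifier requires a 'model_file' parameter")
    model = classify_svm.load_model(model_file)
    tables = [n.payload for n in nodes if n.kind == "features"]
    if not tables:
        raise PipelineError("svm_classifier requires feature input nodes")
    table = features.concat_features(tables) if len(tables) > 1 else tables[0]
    labeled = classify_svm.classify_events(model, table)
    return [DataNode("classified", "events", labeled)]


def _act_bump_modeling(nodes: list[DataNode], params: dict) -> list[DataNode]:
    # registry slot reserved; the method is not implemented
    raise PipelineError("bump_modeling classifier is not implemented")


def default_registry() -> ActivityRegistry:
    reg = ActivityRegistry()
    reg.register("fir_filter", _act_fir_filter,
                 {"low_hz": "float|None", "high_hz": "float|None",
                  "n_taps": "int", "self_convolve": "bool"})
    reg.register("emd_filter", _act_emd_filter,
                 {"first_imf": "int", "n_imfs": "int", "epsilon": "float"})
    reg.register("rms_detector", _act_rms_detector,
                 {f: "float" for f in detect.RmsParams.__dataclass_fields__})
    reg.register("hilbert_detector", _act_hilbert_detector,
                 {f: "float" for f in detect.HilbertParams.__dataclass_fields__})
    reg.register("stockwell_classifier", _act_stockwell_classifier,
                 {f: "float" for f in classify_stockwell.StockwellParams.__dataclass_fields__})
    reg.register("svm_classifier", _act_svm_classifier, {"model_file": "path"})
    reg.register("time_features", _act_time_features, {"selection": "list[str]"})
    reg.register("frequency_features", _act_frequency_features,
                 {"f_lo": "float", "f_hi": "float", "bin_hz": "float",
                  "normalize": "bool"})
    reg.register("bump_modeling", _act_bump_modeling, {})
    return reg


_GLOBAL_REGISTRY = default_registry()


def register_activity(identifier: str, fn: ActivityFn, schema: dict | None = None,
                      registry: ActivityRegistry | None = None) -> None:
    (registry or _GLOBAL_REGISTRY).register(identifier, fn, schema)


# ---------------------------------------------------------------------------
# XML parsing / serialization


def parse_process_definition(
    document: str, registry: ActivityRegistry | None = None
) -> list[ProcessDefinition]:
    """Parse and validate an XML process-definition document."""
    registry = registry or _GLOBAL_REGISTRY
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise PipelineError(f"malformed XML: {exc}") from None
    modules = {}
    module_list = root.find("moduleList")
    if module_list is not None:
        for mod in module_list.findall("module"):
            name = mod.get("moduleName")
            if not name:
                raise PipelineError("moduleList/module missing moduleName")
            modules[name] = mod.get("path", "builtin")
    defs = []
    for proc in root.findall("process"):
        name = proc.get("name")
        if not name:
            raise PipelineError("process element missing name attribute")
        reference = proc.findtext("reference", default="")
        activities = []
        for act in proc.findall("activity"):
            aname = act.get("activityName")
            mref = act.get("moduleRef")
            if not aname or not mref:
                raise PipelineError(
                    f"process {name!r}: activity missing activityName/moduleRef"
                )
            if modules and mref not in modules:
                raise PipelineError(
                    f"process {name!r}: moduleRef {mref!r} not in moduleList"
                )
            inputs = [
                inp.get("ref")
                for inp in act.findall("inputList/input")
                if inp.get("ref")
            ]
            activities.append(ActivitySpec(aname, mref, inputs))
        outputs = [
            out.get("ref")
            for out in proc.findall("outputList/output")
            if out.get("ref")
        ]
        definition = ProcessDefinition(name, reference, activities, outputs)
        definition.validate(registry)
        defs.append(definition)
    if not defs:
        raise PipelineError("document contains no process definitions")
    return defs


def serialize_process_definitions(defs: list[ProcessDefinition]) -> str:
    root = ET.Element("processDefinitions")
    module_list = ET.SubElement(root, "moduleList")
    seen = []
    for d in defs:
        for act in d.activities:
            if act.module_ref not in seen:
                seen.append(act.module_ref)
                ET.SubElement(
                    module_list, "module",
                    moduleName=act.module_ref, path="builtin",
                )
    for d in defs:
        proc = ET.SubElement(root, "process", name=d.name)
        ref = ET.SubElement(proc, "reference")
        ref.text = d.reference
        for act in d.activities:
            el = ET.SubElement(
                proc, "activity",
                activityName=act.activity_name, moduleRef=act.module_ref,
            )
            il = ET.SubElement(el, "inputList")
            for inp in act.input_list:
                ET.SubElement(il, "input", ref=inp)
        ol = ET.SubElement(proc, "outputList")
        for out in d.output_list:
            ET.SubElement(ol, "output", ref=out)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def load_bundled_definitions(
    registry: ActivityRegistry | None = None,
) -> list[ProcessDefinition]:
    text = (
        importlib.resources.files("hfokit.data")
        .joinpath("predefined_processes.xml")
        .read_text()
    )
    return parse_process_definition(text, registry)


def load_default_parameters() -> dict[str, ParameterSet]:
    text = (
        importlib.resources.files("hfokit.data")
        .joinpath("default_parameters.json")
        .read_text()
    )
    doc = json.loads(text)
    return {
        name: ParameterSet(set_id="default", per_activity=entry)
        for name, entry in doc.items()
    }


# ---------------------------------------------------------------------------
# execution


def run_process(
    definition: ProcessDefinition,
    params: ParameterSet | None,
    primary: DataNode,
    registry: ActivityRegistry | None = None,
    monitor: Callable[[str, str], None] | None = None,
) -> ProcessResult:
    """Execute a process on a primary input node.

    Activities run strictly in definition order; each receives the nodes
    named in its input list (or, when the list is empty, every node
    accumulated so far).  On the first failure an ErrorVector is returned
    and no outputs are registered.
    """
    registry = registry or _GLOBAL_REGISTRY
    params = params or ParameterSet()
    definition.validate(registry)
    nodes: dict[str, DataNode] = {PRIMARY_INPUT: primary}
    order: list[str] = [PRIMARY_INPUT]
    for stage, act in enumerate(definition.activities):
        if monitor:
            monitor(act.activity_name, "start")
        fn, _schema = registry.get(act.module_ref)
        if act.input_list:
            inputs = [nodes[ref] for ref in act.input_list]
        else:
            inputs = [nodes[name] for name in order]
        try:
            outputs = fn(inputs, params.activity(act.activity_name))
        except Exception as exc:  # noqa: BLE001 - converted to ErrorVector
            if monitor:
                monitor(act.activity_name, "failed")
            return ProcessResult(
                outputs={},
                all_nodes={},
                error=ErrorVector(act.activity_name, stage, str(exc)),
            )
        merged = outputs[0] if len(outputs) == 1 else DataNode(
            act.activity_name, outputs[0].kind, [o.payload for o in outputs]
        )
        node = DataNode(act.activity_name, merged.kind, merged.payload)
        nodes[act.activity_name] = node
        order.append(act.activity_name)
        if monitor:
            monitor(act.activity_name, "done")
    persisted = {
        ref: nodes[ref]
        for ref in (definition.output_list or [definition.activities[-1].activity_name])
    }
    return ProcessResult(outputs=persisted, all_nodes=nodes, error=None)
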