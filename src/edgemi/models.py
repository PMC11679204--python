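"""Dual-branch attention CNN variants with a flat, freezable layer registry.

The three architectures (FCNNA, XFCNN, LFCNN) share one topology and differ
only in the first-stage temporal filter count F1 and kernel width KE1:

* branch A: temporal convolution (1 x KE1, F1 filters) -> batch norm ->
  spatial depthwise convolution over the electrodes (C x 1, multiplier D) ->
  batch norm -> ELU -> average pooling -> dropout;
* branch B: an overcomplete temporal filter bank — a (1, 1) depthwise
  fan-out into 192 scaled copies of the raw signal -> batch norm -> pooling
  -> separable temporal convolution (1 x KE2) over all electrodes,
  compressed to 24 maps -> batch norm -> ELU -> electrode-average pooling ->
  dropout;
* the branches are concatenated and refined by a CBAM attention block whose
  channel part ends in a pointwise projection down to F1 maps;
* stage two repeats both branches at the second-stage widths (16 filters,
  kernel 64), is refined by a second CBAM block, and feeds a softmax head.

Every layer — including zero-parameter structural nodes (input, branch taps,
concatenations, reshapes) — occupies one slot in a flat 1-based registry so
that freezing "the first L layers" is well defined.  The canonical freeze
levels land on semantic boundaries: 6 = stage-1 temporal filters, 16 = + all
spatial filters (the only channel-count-dependent parameters), 26 = + the
separable convolutions, 44 = + the first attention block's channel part and
projection.  Dimensions were chosen so the three variants reproduce the
published parameter and multiply-accumulate budgets of the reference models.
"""

from __future__ import annotations

import copy
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .data import TrialSet

__all__ = [
    "StageSpec",
    "ModelVariant",
    "FCNNA",
    "XFCNN",
    "LFCNN",
    "get_variant",
    "RegistryEntry",
    "FREEZE_LEVELS",
    "TrainConfig",
    "TrainReport",
    "ModelHandle",
    "build_model",
    "set_freeze_level",
    "count_trainable_params",
    "count_total_params",
    "mac_conv2d",
    "mac_separable_conv2d",
    "mac_depthwise_conv2d",
    "total_mac",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

FREEZE_LEVELS = (0, 6, 16, 26, 44)

SPATIAL_BANK = 192  # branch-B spatial filter count, shared by all variants
DROPOUT_RATE = 0.25
ATTN2_HIDDEN = 4    # second attention block bottleneck (32 maps / 8)


@dataclass(frozen=True)
class StageSpec:
    """One convolutional stage: F1 temporal filters of width KE1, depth
    multiplier D for the spatial depthwise step, separable kernel KE2."""

    F1: int
    KE1: int
    D: int
    KE2: int

    def __post_init__(self):
        for v in (self.F1, self.KE1, self.D, self.KE2):
            if not isinstance(v, int) or v <= 0:
                raise ValueError("stage dimensions must be positive integers")


@dataclass(frozen=True)
class ModelVariant:
    name: str
    stage1: StageSpec
    stage2: StageSpec
    n_classes: int = 4
    uses_channel_selection: bool = False
    spatial_bank: int = SPATIAL_BANK

    @property
    def branch_b_maps(self) -> int:
        """Branch-B compressed width: an eighth of the filter bank."""
        return max(2, self.spatial_bank // 8)

    @property
    def concat_maps(self) -> int:
        return self.stage1.F1 * self.stage1.D + self.branch_b_maps

    @property
    def attn1_hidden(self) -> int:
        return max(2, 5 * self.stage1.F1)

    def with_channel_selection(self, flag: bool = True) -> "ModelVariant":
        return ModelVariant(self.name, self.stage1, self.stage2, self.n_classes,
                            flag, self.spatial_bank)


FCNNA = ModelVariant("FCNNA", StageSpec(96, 60, 2, 16), StageSpec(16, 64, 1, 16))
XFCNN = ModelVariant("XFCNN", StageSpec(16, 60, 2, 16), StageSpec(16, 64, 1, 16))
LFCNN = ModelVariant("LFCNN", StageSpec(8, 48, 2, 16), StageSpec(16, 64, 1, 16))

_VARIANTS = {v.name: v for v in (FCNNA, XFCNN, LFCNN)}


def get_variant(name: str) -> ModelVariant:
    try:
        return _VARIANTS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown variant {name!r}; choose from {sorted(_VARIANTS)}")


@dataclass
class RegistryEntry:
    """One slot of the flat layer registry (1-based ``index``)."""

    index: int
    kind: str
    label: str
    params: List[nn.Param] = field(default_factory=list)
    meta: Optional[Dict[str, int]] = None  # conv shape metadata for MAC
    layer: Optional[nn.Layer] = None
    frozen: bool = False

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params)


# ---------------------------------------------------------------------------
# MAC formulas (printed accounting conventions)


def _check_positive(**kwargs) -> None:
    for k, v in kwargs.items():
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError(f"{k} must be a positive integer, got {v!r}")


def mac_conv2d(K1: int, K2: int, Cin: int, Cout: int, Hout: int, Wout: int) -> int:
    """Multiply-accumulates of a Conv2D layer: K1*K2*Cin*Cout*Hout*Wout."""
    _check_positive(K1=K1, K2=K2, Cin=Cin, Cout=Cout, Hout=Hout, Wout=Wout)
    return K1 * K2 * Cin * Cout * Hout * Wout


def mac_separable_conv2d(K1: int, K2: int, Cin: int, Cout: int,
                         Hout: int, Wout: int) -> int:
    """Multiply-accumulates of a SeparableConv2D: (K1*K2 + Cout)*Cin*Hout*Wout."""
    _check_positive(K1=K1, K2=K2, Cin=Cin, Cout=Cout, Hout=Hout, Wout=Wout)
    return (K1 * K2 + Cout) * Cin * Hout * Wout


def mac_depthwise_conv2d(K1: int, K2: int, Cin: int, D: int,
                         Hout: int, Wout: int) -> int:
    """Multiply-accumulates of a DepthwiseConv2D: K1*K2*Cin*D*Hout*Wout."""
    _check_positive(K1=K1, K2=K2, Cin=Cin, D=D, Hout=Hout, Wout=Wout)
    return K1 * K2 * Cin * D * Hout * Wout


# ---------------------------------------------------------------------------
# model construction


class ModelHandle:
    """A built network: layers, flat registry, and the forward/backward graph."""

    def __init__(self, variant: ModelVariant, n_channels: int, n_samples: int,
                 seed: int):
        v = variant
        s1, s2 = v.stage1, v.stage2
        kmax = max(s1.KE1, s1.KE2, s2.KE1, s2.KE2)
        if n_samples < kmax:
            raise ValueError(
                f"input of {n_samples} samples is narrower than the widest "
                f"kernel ({kmax})"
            )
        if not 1 <= n_channels <= 22:
            raise ValueError("n_channels must be in 1..22")
        self.variant = v
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.seed = seed
        rng = np.random.Generator(np.random.PCG64(seed))

        C, T = n_channels, n_samples
        F1, D1 = s1.F1, s1.D
        SB = v.spatial_bank
        FB = v.branch_b_maps
        CC = v.concat_maps
        F2 = s2.F1
        W1 = T // 8                   # both branches pool by 8 in stage 1
        self.W1 = W1
        Wf = W1 // 2
        if Wf < 1:
            raise ValueError("input too short for the pooling pyramid")
        self.Wf = Wf

        L = {}
        L["convA"] = nn.TemporalConv("convA", 1, F1, s1.KE1, rng)
        L["bnA1"] = nn.BatchNorm("bnA1", F1)
        L["dwA"] = nn.SpatialDepthwiseConv("dwA", F1, C, D1, rng)
        L["bnA2"] = nn.BatchNorm("bnA2", F1 * D1)
        L["eluA"] = nn.ELU()
        L["poolA"] = nn.AvgPoolTime(8)
        L["dropA"] = nn.Dropout(DROPOUT_RATE)
        L["dwB"] = nn.FanOut("dwB", SB, rng)
        L["bnB1"] = nn.BatchNorm("bnB1", SB)
        L["poolB1"] = nn.AvgPoolTime(8)
        L["sepB"] = nn.SeparableTemporalConv("sepB", SB, FB, s1.KE2, rng)
        L["bnB2"] = nn.BatchNorm("bnB2", FB)
        L["eluB"] = nn.ELU()
        L["poolB2"] = nn.ElectrodeMean()
        L["dropB"] = nn.Dropout(DROPOUT_RATE)
        L["ca1"] = nn.CBAMChannel("ca1", CC, v.attn1_hidden, rng)
        L["proj"] = nn.PointwiseConv("proj", CC, F1, rng)
        L["bnP"] = nn.BatchNorm("bnP", F1)
        L["sa1"] = nn.CBAMSpatial("sa1", rng)
        L["conv2A"] = nn.TemporalConv("conv2A", F1, F2, s2.KE1, rng)
        L["bn2A1"] = nn.BatchNorm("bn2A1", F2)
        L["dw2"] = nn.ChannelScale("dw2", F2)
        L["bn2A2"] = nn.BatchNorm("bn2A2", F2)
        L["elu2A"] = nn.ELU()
        L["pool2A"] = nn.AvgPoolTime(2)
        L["drop2A"] = nn.Dropout(DROPOUT_RATE)
        L["sep2"] = nn.SeparableTemporalConv("sep2", F1, F2, s2.KE2, rng)
        L["bn2B"] = nn.BatchNorm("bn2B", F2)
        L["elu2B"] = nn.ELU()
        L["pool2B"] = nn.AvgPoolTime(2)
        L["drop2B"] = nn.Dropout(DROPOUT_RATE)
        L["ca2"] = nn.CBAMChannel("ca2", 2 * F2, ATTN2_HIDDEN, rng)
        L["sa2"] = nn.CBAMSpatial("sa2", rng)
        L["dense"] = nn.Dense("dense", 2 * F2 * Wf, v.n_classes, rng)
        self.layers = L

        self.registry = self._build_registry()
        self._by_param_name = {p.name: p for e in self.registry for p in e.params}

    # -- registry -----------------------------------------------------------

    def _build_registry(self) -> List[RegistryEntry]:
        v, L = self.variant, self.layers
        C, T = self.n_channels, self.n_samples
        s1, s2 = v.stage1, v.stage2
        W1, Wf = self.W1, self.Wf
        SB, FB, CC, F1, F2 = (v.spatial_bank, v.branch_b_maps, v.concat_maps,
                              s1.F1, s2.F1)

        def conv_meta(K1, K2, Cin, Cout, Hout, Wout, op="conv"):
            return dict(K1=K1, K2=K2, Cin=Cin, Cout=Cout, Hout=Hout,
                        Wout=Wout, op=op)

        rows: List[Tuple[str, str, object, object]] = [
            # (kind, label, layer key or None, meta or None)
            ("marker", "input", None, None),
            ("temporal_conv", "stage1 temporal conv (branch A)", "convA",
             conv_meta(1, s1.KE1, 1, F1, C, T)),
            ("batch_norm", "batch norm", "bnA1", None),
            ("marker", "branch tap", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),                       # -> 6
            ("spatial_depthwise_conv", "stage1 spatial depthwise (branch A)",
             "dwA", dict(K1=C, K2=1, Cin=F1, D=s1.D, Hout=1, Wout=T,
                         op="depthwise")),
            ("batch_norm", "batch norm", "bnA2", None),
            ("activation", "ELU", "eluA", None),
            ("pooling", "average pool (1,8)", "poolA", None),
            ("dropout", "dropout", "dropA", None),
            ("spatial_depthwise_conv", "temporal filter-bank fan-out (branch B)",
             "dwB", dict(K1=1, K2=1, Cin=1, D=SB, Hout=C, Wout=T,
                         op="depthwise")),
            ("batch_norm", "batch norm", "bnB1", None),
            ("pooling", "average pool (1,8)", "poolB1", None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),                       # -> 16
            ("separable_conv", "stage1 separable temporal conv (branch B)",
             "sepB", conv_meta(1, s1.KE2, SB, FB, C, T // 8, op="separable")),
            ("batch_norm", "batch norm", "bnB2", None),
            ("activation", "ELU", "eluB", None),
            ("pooling", "electrode-average pool", "poolB2", None),
            ("dropout", "dropout", "dropB", None),
            ("marker", "concatenate branches", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),                       # -> 26
            ("attention_sub", "attention 1: global average pool", None, None),
            ("attention_sub", "attention 1: global max pool", None, None),
            ("attention_sub", "attention 1: shared dense reduce",
             ("ca1", ("W1", "b1")), None),
            ("activation", "attention 1: ReLU", None, None),
            ("attention_sub", "attention 1: shared dense expand",
             ("ca1", ("W2", "b2")), None),
            ("attention_sub", "attention 1: add", None, None),
            ("attention_sub", "attention 1: sigmoid", None, None),
            ("attention_sub", "attention 1: channel scale", None, None),
            ("attention_sub", "attention 1: output projection", "proj",
             conv_meta(1, 1, CC, F1, 1, W1)),
            ("batch_norm", "batch norm", "bnP", None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),
            ("marker", "reshape", None, None),                       # -> 44
            ("attention_sub", "attention 1: spatial mean map", None, None),
            ("attention_sub", "attention 1: spatial max map", None, None),
            ("attention_sub", "attention 1: concat maps", None, None),
            ("attention_sub", "attention 1: spatial conv (1,7)", "sa1",
             conv_meta(1, 7, 2, 1, 1, W1)),
            ("attention_sub", "attention 1: sigmoid", None, None),
            ("attention_sub", "attention 1: spatial scale", None, None),
            ("temporal_conv", "stage2 temporal conv (branch A)", "conv2A",
             conv_meta(1, s2.KE1, F1, F2, 1, W1)),
            ("batch_norm", "batch norm", "bn2A1", None),
            ("spatial_depthwise_conv", "stage2 depthwise (1,1)", "dw2",
             dict(K1=1, K2=1, Cin=F2, D=s2.D, Hout=1, Wout=W1, op="depthwise")),
            ("batch_norm", "batch norm", "bn2A2", None),
            ("activation", "ELU", "elu2A", None),
            ("pooling", "average pool (1,2)", "pool2A", None),
            ("dropout", "dropout", "drop2A", None),
            ("separable_conv", "stage2 separable temporal conv (branch B)",
             "sep2", conv_meta(1, s2.KE2, F1, F2, 1, W1, op="separable")),
            ("batch_norm", "batch norm", "bn2B", None),
            ("activation", "ELU", "elu2B", None),
            ("pooling", "average pool (1,2)", "pool2B", None),
            ("dropout", "dropout", "drop2B", None),
            ("marker", "concatenate branches", None, None),
            ("attention_sub", "attention 2: global average pool", None, None),
            ("attention_sub", "attention 2: global max pool", None, None),
            ("attention_sub", "attention 2: shared dense reduce",
             ("ca2", ("W1", "b1")), None),
            ("activation", "attention 2: ReLU", None, None),
            ("attention_sub", "attention 2: shared dense expand",
             ("ca2", ("W2", "b2")), None),
            ("attention_sub", "attention 2: add", None, None),
            ("attention_sub", "attention 2: sigmoid", None, None),
            ("attention_sub", "attention 2: channel scale", None, None),
            ("attention_sub", "attention 2: spatial mean map", None, None),
            ("attention_sub", "attention 2: spatial max map", None, None),
            ("attention_sub", "attention 2: concat maps", None, None),
            ("attention_sub", "attention 2: spatial conv (1,7)", "sa2",
             conv_meta(1, 7, 2, 1, 1, Wf)),
            ("attention_sub", "attention 2: sigmoid", None, None),
            ("attention_sub", "attention 2: spatial scale", None, None),
            ("marker", "flatten", None, None),
            ("dense", "dense softmax head", "dense", None),
            ("softmax", "softmax", None, None),
        ]

        registry = []
        for i, (kind, label, ref, meta) in enumerate(rows, start=1):
            params: List[nn.Param] = []
            layer = None
            if isinstance(ref, str):
                layer = self.layers[ref]
                params = list(layer.params)
            elif isinstance(ref, tuple):
                key, names = ref
                layer = self.layers[key]
                params = [getattr(layer, n) for n in names]
            registry.append(RegistryEntry(i, kind, label, params, meta, layer))
        return registry

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Logits for a batch shaped (n, 1, channels, samples)."""
        L = self.layers
        a = L["convA"].forward(x, training)
        a = L["bnA1"].forward(a, training)
        a = L["dwA"].forward(a, training)
        a = L["bnA2"].forward(a, training)
        a = L["eluA"].forward(a, training)
        a = L["poolA"].forward(a, training)
        a = L["dropA"].forward(a, training, rng)
        b = L["dwB"].forward(x, training)
        b = L["bnB1"].forward(b, training)
        b = L["poolB1"].forward(b, training)
        b = L["sepB"].forward(b, training)
        b = L["bnB2"].forward(b, training)
        b = L["eluB"].forward(b, training)
        b = L["poolB2"].forward(b, training)
        b = L["dropB"].forward(b, training, rng)
        w = min(a.shape[3], b.shape[3])
        self._a_w, self._b_w = a.shape[3], b.shape[3]
        z = np.concatenate([a[:, :, :, :w], b[:, :, :, :w]], axis=1)
        self._na = a.shape[1]
        z = L["ca1"].forward(z, training)
        z = L["proj"].forward(z, training)
        z = L["bnP"].forward(z, training)
        z = L["sa1"].forward(z, training)
        p = L["conv2A"].forward(z, training)
        p = L["bn2A1"].forward(p, training)
        p = L["dw2"].forward(p, training)
        p = L["bn2A2"].forward(p, training)
        p = L["elu2A"].forward(p, training)
        p = L["pool2A"].forward(p, training)
        p = L["drop2A"].forward(p, training, rng)
        q = L["sep2"].forward(z, training)
        q = L["bn2B"].forward(q, training)
        q = L["elu2B"].forward(q, training)
        q = L["pool2B"].forward(q, training)
        q = L["drop2B"].forward(q, training, rng)
        z2 = np.concatenate([p, q], axis=1)
        self._np2 = p.shape[1]
        z2 = L["ca2"].forward(z2, training)
        z2 = L["sa2"].forward(z2, training)
        self._flat_shape = z2.shape
        flat = z2.reshape(z2.shape[0], -1)
        return L["dense"].forward(flat, training)

    def backward(self, g_logits: np.ndarray) -> None:
        """Backpropagate; gradient flow stops once every remaining upstream
        entry is frozen (frozen prefixes cost no backward computation, which
        is where freezing saves retraining time)."""
        frozen = {e.index for e in self.registry if e.frozen}
        need_attn1 = any(i not in frozen for i in range(1, 45))
        need_branches = any(i not in frozen for i in range(1, 27))
        L = self.layers
        g = L["dense"].backward(g_logits)
        g = g.reshape(self._flat_shape)
        g = L["sa2"].backward(g)
        g = L["ca2"].backward(g)
        gp, gq = g[:, :self._np2], g[:, self._np2:]
        gp = L["drop2A"].backward(gp)
        gp = L["pool2A"].backward(gp)
        gp = L["elu2A"].backward(gp)
        gp = L["bn2A2"].backward(gp)
        gp = L["dw2"].backward(gp)
        gp = L["bn2A1"].backward(gp)
        gz = L["conv2A"].backward(gp)
        gq = L["drop2B"].backward(gq)
        gq = L["pool2B"].backward(gq)
        gq = L["elu2B"].backward(gq)
        gq = L["bn2B"].backward(gq)
        gz = gz + L["sep2"].backward(gq)
        gz = L["sa1"].backward(gz)
        if not need_attn1:
            return
        gz = L["bnP"].backward(gz)
        gz = L["proj"].backward(gz)
        gz = L["ca1"].backward(gz)
        if not need_branches:
            return
        ga, gb = gz[:, :self._na], gz[:, self._na:]
        if ga.shape[3] < self._a_w:
            ga = np.pad(ga, [(0, 0), (0, 0), (0, 0), (0, self._a_w - ga.shape[3])])
        if gb.shape[3] < self._b_w:
            gb = np.pad(gb, [(0, 0), (0, 0), (0, 0), (0, self._b_w - gb.shape[3])])
        ga = L["dropA"].backward(ga)
        ga = L["poolA"].backward(ga)
        ga = L["eluA"].backward(ga)
        ga = L["bnA2"].backward(ga)
        ga = L["dwA"].backward(ga)
        ga = L["bnA1"].backward(ga)
        L["convA"].backward(ga)
        gb = L["dropB"].backward(gb)
        gb = L["poolB2"].backward(gb)
        gb = L["eluB"].backward(gb)
        gb = L["bnB2"].backward(gb)
        gb = L["sepB"].backward(gb)
        gb = L["poolB1"].backward(gb)
        gb = L["bnB1"].backward(gb)
        L["dwB"].backward(gb)

    # -- parameters and weights --------------------------------------------

    @property
    def all_params(self) -> List[nn.Param]:
        return [p for e in self.registry for p in e.params]

    def get_weights(self) -> Dict[str, np.ndarray]:
        out = {p.name: p.value.copy() for p in self.all_params}
        for key, layer in self.layers.items():
            if isinstance(layer, nn.BatchNorm):
                out[f"{key}._running_mean"] = layer.running_mean.copy()
                out[f"{key}._running_var"] = layer.running_var.copy()
        return out

    def set_weights(self, weights: Dict[str, np.ndarray]) -> None:
        for p in self.all_params:
            p.value = np.array(weights[p.name], dtype=np.float32)
        for key, layer in self.layers.items():
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = np.array(weights[f"{key}._running_mean"],
                                              dtype=np.float32)
                layer.running_var = np.array(weights[f"{key}._running_var"],
                                             dtype=np.float32)

    def copy(self) -> "ModelHandle":
        clone = ModelHandle(self.variant, self.n_channels, self.n_samples,
                            self.seed)
        clone.set_weights(self.get_weights())
        clone.pin_bn_stats = getattr(self, "pin_bn_stats", False)
        for e_src, e_dst in zip(self.registry, clone.registry):
            e_dst.frozen = e_src.frozen
        clone._sync_freeze_flags()
        return clone

    def _sync_freeze_flags(self) -> None:
        pin = getattr(self, "pin_bn_stats", False)
        for e in self.registry:
            for p in e.params:
                p.frozen = e.frozen
            if isinstance(e.layer, nn.BatchNorm):
                e.layer.frozen = e.frozen or pin

    @property
    def freeze_level(self) -> int:
        level = 0
        for e in self.registry:
            if e.frozen:
                level = e.index
            else:
                break
        return level


def build_model(variant: ModelVariant, n_channels: int, n_samples: int,
                seed: int = 0) -> ModelHandle:
    """Construct a variant for the given input shape with seeded weights."""
    return ModelHandle(variant, n_channels, n_samples, seed)


def set_freeze_level(model: ModelHandle, level: int) -> ModelHandle:
    """Freeze registry entries with index <= level (prefix freezing)."""
    if not 0 <= level <= len(model.registry):
        raise ValueError(
            f"freeze level {level} outside 0..{len(model.registry)}"
        )
    for e in model.registry:
        e.frozen = e.index <= level
    model._sync_freeze_flags()
    return model


def count_trainable_params(model: ModelHandle) -> int:
    return sum(e.param_count for e in model.registry if not e.frozen)


def count_total_params(model: ModelHandle) -> int:
    return sum(e.param_count for e in model.registry)


def total_mac(model: ModelHandle) -> int:
    """Sum the printed MAC formulas over the registry's conv entries."""
    total = 0
    for e in model.registry:
        if e.meta is None:
            continue
        m = e.meta
        if m["op"] == "conv":
            total += mac_conv2d(m["K1"], m["K2"], m["Cin"], m["Cout"],
                                m["Hout"], m["Wout"])
        elif m["op"] == "separable":
            total += mac_separable_conv2d(m["K1"], m["K2"], m["Cin"],
                                          m["Cout"], m["Hout"], m["Wout"])
        elif m["op"] == "depthwise":
            total += mac_depthwise_conv2d(m["K1"], m["K2"], m["Cin"], m["D"],
                                          m["Hout"], m["Wout"])
        else:  # pragma: no cover
            raise ValueError(f"entry {e.index} has unknown op {m['op']}")
    return total


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    learning_rate: float = 0.0009
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass
class TrainReport:
    losses: List[float] = field(default_factory=list)
    monitored_accuracy: List[float] = field(default_factory=list)
    best_epoch: int = -1
    best_accuracy: float = float("nan")
    wall_time_s: float = 0.0


def _prepare(trials: TrialSet) -> Tuple[np.ndarray, np.ndarray]:
    """Per-trial standardization into network layout.

    Channel means are removed but a single per-trial scale is used, so the
    relative band power across channels — the discriminative ERD feature —
    is preserved.
    """
    x = trials.data.astype(np.float32)
    x = x - x.mean(axis=2, keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True) + 1e-6
    x = x / sd
    return x[:, None, :, :], trials.labels - 1


def train(model: ModelHandle, trials: TrialSet, config: TrainConfig) -> TrainReport:
    """Train in place; keeps the weights of the best-monitored epoch.

    The monitored quantity is the accuracy on the training trials evaluated
    in inference mode at the end of each epoch (the checkpoint-callback
    convention).  Frozen registry entries are bit-identical afterwards.
    """
    report = TrainReport()
    if config.epochs == 0:
        return report
    x, y = _prepare(trials)
    n = len(y)
    if n < 1:
        raise ValueError("no trials to train on")
    if len(np.unique(y)) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    counts = np.bincount(y, minlength=4)
    if counts.max() > 0 and counts[counts > 0].min() * 3 < counts.max():
        warnings.warn("training labels are strongly unbalanced", stacklevel=2)

    rng = np.random.Generator(np.random.PCG64(config.seed))
    opt = nn.Adam(model.all_params, lr=config.learning_rate)
    batch = max(1, min(config.batch_size, n))
    t0 = time.perf_counter()
    best_weights = None
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, batch):
            idx = order[i0:i0 + batch]
            opt.zero_grad()
            logits = model.forward(x[idx], training=True, rng=rng)
            probs = nn.softmax(logits)
            losses.append(nn.cross_entropy(probs, y[idx]))
            g = probs.copy()
            g[np.arange(len(idx)), y[idx]] -= 1.0
            model.backward(g / len(idx))
            opt.step()
        acc = float((_predict_indices(model, x) == y).mean())
        report.losses.append(float(np.mean(losses)))
        report.monitored_accuracy.append(acc)
        if best_weights is None or acc > report.best_accuracy:
            report.best_accuracy = acc
            report.best_epoch = epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    report.wall_time_s = time.perf_counter() - t0
    return report


def _predict_indices(model: ModelHandle, x: np.ndarray,
                     batch: int = 64) -> np.ndarray:
    out = []
    for i0 in range(0, len(x), batch):
        out.append(np.argmax(model.forward(x[i0:i0 + batch]), axis=1))
    return np.concatenate(out)


def predict(model: ModelHandle, trials: TrialSet,
            batch: int = 64) -> Tuple[np.ndarray, np.ndarray]:
    """Labels (1..4) and class probabilities for a trial set."""
    if trials.n_channels != model.n_channels or trials.n_samples != model.n_samples:
        raise ValueError(
            f"trials of shape ({trials.n_channels} ch, {trials.n_samples} samp) "
            f"do not match model input ({model.n_channels}, {model.n_samples})"
        )
    x, _ = _prepare(trials)
    probs = []
    for i0 in range(0, len(x), batch):
        probs.append(nn.softmax(model.forward(x[i0:i0 + batch])))
    probs = np.concatenate(probs)
    return np.argmax(probs, axis=1) + 1, probs


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: ModelHandle, directory) -> None:
    """Write a registry manifest (JSON) plus weight arrays, round-trippable."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    v = model.variant
    manifest = {
        "variant": {
            "name": v.name,
            "stage1": [v.stage1.F1, v.stage1.KE1, v.stage1.D, v.stage1.KE2],
            "stage2": [v.stage2.F1, v.stage2.KE1, v.stage2.D, v.stage2.KE2],
            "n_classes": v.n_classes,
            "uses_channel_selection": v.uses_channel_selection,
            "spatial_bank": v.spatial_bank,
        },
        "n_channels": model.n_channels,
        "n_samples": model.n_samples,
        "seed": model.seed,
        "frozen": [e.index for e in model.registry if e.frozen],
        "registry": [
            {"index": e.index, "kind": e.kind, "label": e.label,
             "param_count": e.param_count}
            for e in model.registry
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(directory / "weights.npz", **model.get_weights())


def load_checkpoint(directory) -> ModelHandle:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    mv = manifest["variant"]
    variant = ModelVariant(
        mv["name"], StageSpec(*mv["stage1"]), StageSpec(*mv["stage2"]),
        mv["n_classes"], mv["uses_channel_selection"], mv["spatial_bank"],
    )
    model = ModelHandle(variant, manifest["n_channels"], manifest["n_samples"],
                        manifest["seed"])
    with np.load(directory / "weights.npz") as data:
        model.set_weights({k: data[k] for k in data.files})
    frozen = set(manifest["frozen"])
    for e in model.registry:
        e.frozen = e.index in frozen
    model._sync_freeze_flags()
    return model
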