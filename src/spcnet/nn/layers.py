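"""Parameterized layers and a tiny module system on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from spcnet.nn.autodiff import Tensor, conv2d, relu

__all__ = ["ParamStore", "Module", "Conv2d"]


class ParamStore:
    """Ordered, named registry of trainable tensors."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def register(self, name: str, t: Tensor) -> Tensor:
        if name in self._params:
            raise KeyError(f"duplicate parameter name: {name}")
        t.requires_grad = True
        self._params[name] = t
        return t

    def items(self):
        return self._params.items()

    def tensors(self) -> list[Tensor]:
        return list(self._params.values())

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self._params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self._params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, v in self._params.items():
            arr = np.asarray(state[k], dtype=v.data.dtype)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def zero_grad(self) -> None:
        for t in self._params.values():
            t.grad = None


class Module:
    """Base class: subclasses build their parameters in a shared ParamStore."""

    def __init__(self, store: ParamStore, name: str):
        self.store = store
        self.name = name

    def _param(self, suffix: str, data: np.ndarray) -> Tensor:
        return self.store.register(f"{self.name}.{suffix}", Tensor(data))


class Conv2d(Module):
    """3x3/1x1 'same' convolution with He-normal init and optional ReLU."""

    def __init__(
        self,
        store: ParamStore,
        name: str,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        zero_init: bool = False,
    ):
        super().__init__(store, name)
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        w = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale).astype(dtype)
        self.weight = self._param("weight", w)
        self.bias = self._param("bias", np.zeros(out_ch, dtype=dtype))
        self.dilation = dilation

    def __call__(self, x: Tensor, activate: bool = False) -> Tensor:
        y = conv2d(x, self.weight, self.bias, dilation=self.dilation)
        return relu(y) if activate else y
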