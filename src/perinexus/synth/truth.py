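"""Ground-truth container shared by all synthetic generators."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any


def _jsonable(obj: Any) -> Any:
    """Coerce numpy scalars/arrays and dataclasses to plain JSON types."""
    import numpy as np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class SceneTruth:
    """Per-modality ground truth for a generated scene.

    Parameters
    ----------
    modality:
        One of ``storm``, ``optical``, ``ecis``, ``membranes``, ``ecg``.
    seed:
        The seed the scene was generated with (recorded for reproducibility).
    params:
        The generator configuration, as a plain dict.
    records:
        Modality-specific ground truth: planted clusters, wave parameters,
        resistance trajectory, separation function samples, or beat list.
    """

    modality: str
    seed: int
    params: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)

    def to_json(self, path=None, **kwargs) -> str:
        payload = json.dumps(_jsonable(self), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "SceneTruth":
        import os

        if os.path.exists(source):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = json.loads(source)
        return cls(**data)
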