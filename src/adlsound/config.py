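"""YAML node configuration.

Flat sections mirror the pipeline stages::

    name: bath-node
    location: bathroom
    capture: {wake_threshold: 0.01, stop_silence_s: 5.0}
    post:
      threshold: 0.5
      window_size: 7
      tolerance_continuous: 10
      tolerance_instant: 4
      min_duration: 0.5
      min_confidence: 0.0
    allowed_labels: null          # null -> class list minus location exclusions
    exclusions:                   # optional override of the location table
      bathroom: [tv, microwave, cooking]
    use_quantized: false
"""

from __future__ import annotations

import yaml

from .hub import DEFAULT_EXCLUSIONS, NodeConfig
from .postprocess import PostConfig


def node_config_from_dict(d: dict) -> NodeConfig:
    post_kwargs = dict(d.get("post", {}))
    if "labels" in post_kwargs:
        post_kwargs["labels"] = tuple(post_kwargs["labels"])
    if "instant_labels" in post_kwargs:
        post_kwargs["instant_labels"] = frozenset(post_kwargs["instant_labels"])
    post = PostConfig(**post_kwargs)
    capture = d.get("capture", {})
    exclusions = None
    if "exclusions" in d:
        exclusions = dict(DEFAULT_EXCLUSIONS)
        exclusions.update({loc: tuple(labels) for loc, labels in d["exclusions"].items()})
    allowed = d.get("allowed_labels")
    return NodeConfig(
        name=d.get("name", "node0"),
        location=d.get("location", "bathroom"),
        allowed_labels=tuple(allowed) if allowed is not None else None,
        wake_threshold=capture.get("wake_threshold", 0.01),
        stop_silence_s=capture.get("stop_silence_s", 5.0),
        use_quantized=d.get("use_quantized", False),
        post=post,
        exclusions=exclusions,
    )


def load_node_config(path: str) -> NodeConfig:
    with open(path) as fh:
        return node_config_from_dict(yaml.safe_load(fh) or {})
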