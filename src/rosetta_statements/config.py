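"""Runtime configuration (YAML): instance-IRI base, vocabulary namespace,
default dialect."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .model import DEFAULT_INSTANCE_BASE
from .vocab import DEFAULT_NAMESPACE, RosettaVocabulary


@dataclass(frozen=True)
class Config:
    base_iri: str = DEFAULT_INSTANCE_BASE
    vocab_namespace: str = DEFAULT_NAMESPACE
    default_dialect: str = "full"

    def vocabulary(self) -> RosettaVocabulary:
        return RosettaVocabulary(self.vocab_namespace)


def load_config(path: Optional[Union[str, Path]]) -> Config:
    if path is None:
        return Config()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return Config(
        base_iri=data.get("base_iri", DEFAULT_INSTANCE_BASE),
        vocab_namespace=data.get("vocab_namespace", DEFAULT_NAMESPACE),
        default_dialect=data.get("default_dialect", "full"),
    )
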