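"""Tunable thresholds and tool configuration.

All numeric cutoffs used when interpreting homology evidence live in
:class:`Thresholds`; they are deliberately explicit because the annotation
guide they feed ("is this hit significant?", "does the alignment cover
all/most of the query?") is qualitative and every boundary here is an
interpretation.  Each default is documented in docs/methods.md and echoed in
recommendation rationales so a curator can audit which cutoffs produced a
suggestion.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError


@dataclass(frozen=True)
class Thresholds:
    """Numeric cutoffs for evidence classification and terminase detection.

    evalue_significant / evalue_moderate
        BLAST-style hits with e-value <= ``evalue_significant`` are
        *significant*; between the two bounds, *moderate*; above
        ``evalue_moderate``, ignored.
    hh_prob_significant / hh_prob_moderate
        HMM-HMM search probability (0-100) analogues of the above.
    coverage_all_most / coverage_some
        Fraction of the query (or subject) covered by the alignment that
        counts as "all/most", and the floor below which coverage is
        negligible rather than "some".
    length_similar
        min(len_q, len_s) / max(len_q, len_s) at or above this is "similar
        length".
    consistency_jaccard / consistency_top_k
        Hit labels agree when the Jaccard similarity of their normalized
        token sets reaches the cutoff; within one database the top-k hits are
        compared pairwise.
    terminase_max_evalue / terminase_min_qcov
        "Enough evidence" of a terminase gene during phage upload.
    search_max_evalue
        Reporting threshold of the builtin protein search.
    """

    evalue_significant: float = 1e-5
    evalue_moderate: float = 1e-2
    hh_prob_significant: float = 80.0
    hh_prob_moderate: float = 50.0
    coverage_all_most: float = 0.8
    coverage_some: float = 0.35
    length_similar: float = 0.8
    consistency_jaccard: float = 0.5
    consistency_top_k: int = 5
    terminase_max_evalue: float = 1e-10
    terminase_min_qcov: float = 0.5
    search_max_evalue: float = 10.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class Config:
    """Runtime configuration for the CLI and orchestration layers.

    ``adapters`` maps an adapter name (e.g. "glimmer") to a definition dict;
    see :mod:`manna.ingest`.  ``test_mode`` pins timestamps so exports are
    byte-reproducible.
    """

    store_path: str = "manna.sqlite"
    terminase_db: str | None = None
    adapters: dict[str, dict] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    test_mode: bool = False

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        """Read a TOML config file; unknown keys are rejected."""
        with open(path, "rb") as fh:
            try:
                raw = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
        cfg = cls()
        thr_names = {f.name for f in dataclasses.fields(Thresholds)}
        for key, value in raw.items():
            if key == "thresholds":
                bad = set(value) - thr_names
                if bad:
                    raise ConfigurationError(f"unknown threshold keys: {sorted(bad)}")
                cfg.thresholds = Thresholds(**value)
            elif key in ("store_path", "terminase_db", "test_mode"):
                setattr(cfg, key, value)
            elif key == "adapters":
                cfg.adapters = dict(value)
            else:
                raise ConfigurationError(f"unknown config key: {key!r}")
        return cfg
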