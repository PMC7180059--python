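"""Readers/writers for the pipeline's standard formats and configuration.

Trees travel as Newick (dendropy), tables as comma-separated UTF-8 CSV with
"." decimals. Every table written by the pipeline carries a comment header
naming the seed and tolerance set that produced it, so outputs are traceable
to their run.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import pandas as pd
import yaml


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree (path or literal string).

    Raises ValueError with the parser's position information on malformed
    input.
    """
    text = None
    p = Path(str(path_or_string))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        text = None
    if text is None:
        text = str(path_or_string)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick input: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write Newick with 12-significant-digit branch lengths."""
    out = tree.as_string(
        schema="newick",
        real_value_format_specifier=".12g",
        suppress_rooting=True,
    )
    Path(path).write_text(out)


def write_table(df: pd.DataFrame, path, header_fields: Optional[dict] = None,
                index: bool = True) -> None:
    """Write a CSV with '#'-prefixed provenance header lines."""
    buf = _io.StringIO()
    for key, value in (header_fields or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, index=index)
    Path(path).write_text(buf.getvalue())


def read_table(path, index_col=0) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (skips '#' headers)."""
    return pd.read_csv(path, comment="#", index_col=index_col)


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end pipeline run."""

    output_dir: str = "chemevol_out"
    tree_path: Optional[str] = None
    features_path: Optional[str] = None
    traits_path: Optional[str] = None
    plate_path: Optional[str] = None
    library_path: Optional[str] = None
    sample_metadata_path: Optional[str] = None  # sample -> species/experiment map
    mz_tol: float = 0.005
    rt_tol: float = 0.05
    seed: int = 0
    n_perm_mantel: int = 1000  # Mantel permutations
    n_sim_k: int = 10000  # Blomberg-K simulations
    n_boot: int = 10000  # multiscale bootstrap iterations
    ward_variant: str = "ward.D"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("n_perm_mantel", "n_sim_k", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mz_tol <= 0 or self.rt_tol <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"}
        data.update(self.extra)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def header_fields(self) -> dict:
        return {
            "seed": self.seed,
            "mz_tol": self.mz_tol,
            "rt_tol": self.rt_tol,
            "n_perm_mantel": self.n_perm_mantel,
            "n_sim_k": self.n_sim_k,
            "n_boot": self.n_boot,
        }
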