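"""End-to-end run: read matrix -> preprocess -> all-pairs LSA -> export."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .core import LagWindow
from .network import EXPORT_FORMATS, all_pairs_lsa, export_network
from .preprocess import filter_zero_rows, interpolate_missing, read_matrix, standardize

log = logging.getLogger("lsanet")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str
    output_prefix: str
    delimiter: str = "\t"
    D: int = 3
    alpha: float = 0.001
    lsa_threshold: float = 0.0
    correction: str = "bonferroni"
    bound_variant: str = "table"
    perms: int = 0
    workers: int = 1
    seed: int = 0
    max_zero_fraction: float = 0.25
    formats: tuple[str, ...] = ("edge_attr_tsv",)
    all_edges: bool = False

    def __post_init__(self) -> None:
        bad = [f for f in self.formats if f not in EXPORT_FORMATS]
        if bad:
            raise ValueError(f"unknown formats {bad}; choose from {EXPORT_FORMATS}")


_SUFFIX = {"sif": ".sif", "edge_attr_tsv": ".edges.tsv", "graphml": ".graphml"}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write edge files plus a run report.

    Returns the report dictionary; writes ``<prefix><fmt suffix>`` per
    requested format, ``<prefix>.report.json`` and ``<prefix>.report.txt``.
    Partial outputs are removed if any stage fails.
    """
    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        raw = read_matrix(config.input_path, delimiter=config.delimiter)
        log.info("read %d series x %d time points", *raw.shape)
        complete = interpolate_missing(raw)
        kept, removed = filter_zero_rows(complete, config.max_zero_fraction)
        if removed:
            log.info("zero-fraction filter removed %d series", len(removed))
        series = standardize(kept)
        table = all_pairs_lsa(
            series,
            lag=LagWindow(config.D),
            alpha=config.alpha,
            correction=config.correction,
            lsa_threshold=config.lsa_threshold,
            bound_variant=config.bound_variant,
            workers=config.workers,
            perms=config.perms,
            seed=config.seed,
        )
        for fmt in config.formats:
            out = prefix.with_name(prefix.name + _SUFFIX[fmt])
            export_network(table, fmt, out, all_edges=config.all_edges)
            written.append(out)
        report = {
            "version": __version__,
            "input": str(config.input_path),
            "series_read": raw.shape[0],
            "series_removed": len(removed),
            "series_analyzed": table.meta["m"],
            "n": table.meta["n"],
            "D": config.D,
            "alpha": config.alpha,
            "correction": config.correction,
            "corrected_alpha": table.meta["corrected_alpha"],
            "lsa_threshold": config.lsa_threshold,
            "bound_variant": config.bound_variant,
            "perms": config.perms,
            "workers": config.workers,
            "seed": config.seed,
            "num_pairs": table.meta["num_pairs"],
            "num_significant": table.meta["num_significant"],
            "outputs": [str(p) for p in written],
        }
        json_path = prefix.with_name(prefix.name + ".report.json")
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(json_path)
        txt_path = prefix.with_name(prefix.name + ".report.txt")
        with open(txt_path, "w") as fh:
            for key in sorted(report):
                fh.write(f"{key}\t{report[key]}\n")
        written.append(txt_path)
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
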