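"""Reading and writing the pipeline's plain-text formats.

Event tables are CSV with the fixed column schema; MFI matrices are CSV
(interactions as rows, sample ids as header) with a JSON sidecar for the
per-sample annotations; truth tables are JSON; panel and design
configurations round-trip through YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .containers import EVENT_COLUMNS, MFIMatrix, validate_event_table
from .synthdata import IPAntibody, PanelConfig, SimulationDesign


def write_event_table(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_event_table(events).to_csv(path, index=False)
    return path


def read_event_table(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    return validate_event_table(events[EVENT_COLUMNS])


def write_mfi_matrix(matrix: MFIMatrix, path: str | Path) -> Path:
    """CSV matrix plus ``<stem>.samples.json`` annotation sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, index_label="interaction")
    sidecar = {
        "log2_scale": matrix.log2_scale,
        "samples": {
            str(sid): {k: _plain(v) for k, v in row.items()}
            for sid, row in matrix.samples.iterrows()
        },
    }
    path.with_suffix(".samples.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_mfi_matrix(path: str | Path) -> MFIMatrix:
    path = Path(path)
    values = pd.read_csv(path, index_col="interaction")
    values.index.name = None
    sidecar = json.loads(path.with_suffix(".samples.json").read_text())
    samples = pd.DataFrame.from_dict(sidecar["samples"], orient="index")
    samples.index.name = "sample_id"
    return MFIMatrix(values, samples.loc[values.columns], sidecar["log2_scale"])


def write_panel(panel: PanelConfig, path: str | Path) -> Path:
    payload = {
        "classification_sd": panel.classification_sd,
        "ip_antibodies": [
            {
                "name": ab.name,
                "region": int(ab.region),
                "centroid": [float(x) for x in ab.centroid],
            }
            for ab in panel.ip_antibodies
        ],
        "probe_antibodies": list(panel.probe_antibodies),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
    return Path(path)


def read_panel(path: str | Path) -> PanelConfig:
    payload = yaml.safe_load(Path(path).read_text())
    ips = [
        IPAntibody(ab["name"], int(ab["region"]), tuple(ab["centroid"]))
        for ab in payload["ip_antibodies"]
    ]
    return PanelConfig(
        ips, list(payload["probe_antibodies"]), float(payload["classification_sd"])
    )


def write_design(design: SimulationDesign, path: str | Path) -> Path:
    payload = asdict(design)
    payload["conditions"] = list(payload["conditions"])
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
    return Path(path)


def read_design(path: str | Path) -> SimulationDesign:
    payload = yaml.safe_load(Path(path).read_text())
    payload["conditions"] = tuple(payload["conditions"])
    return SimulationDesign(**payload)


def write_anc_result(result, prefix: str | Path) -> tuple[Path, Path]:
    """Tidy CSV of per-experiment comparisons plus a JSON hit set."""
    prefix = Path(prefix)
    comparisons_path = prefix.with_suffix(".comparisons.csv")
    result.comparisons.to_csv(comparisons_path, index=False)
    hits_path = prefix.with_suffix(".hits.json")
    payload = {
        "alpha": {
            "alpha_family": result.alpha.alpha_family,
            "n_comparisons": result.alpha.n_comparisons,
            "alpha_bonferroni": result.alpha.alpha_bonferroni,
            "alpha_empirical": result.alpha.alpha_empirical,
            "alpha_adj": result.alpha.alpha_adj,
        },
        "hits": [
            {
                "interaction": h.interaction,
                "experiments_significant": [_plain(e) for e in h.experiments_significant],
                "replication_fraction": h.replication_fraction,
                "direction": h.direction,
                "mean_fold_change": h.mean_fold_change,
                "mean_log2_fc": h.mean_log2_fc,
                "floor_limited": h.floor_limited,
            }
            for h in result.hits
        ],
    }
    hits_path.write_text(json.dumps(payload, indent=1))
    return comparisons_path, hits_path


def write_module_set(modules, prefix: str | Path) -> list[Path]:
    """Module assignment, eigengene and module-trait tables as CSV."""
    prefix = Path(prefix)
    written = []
    assignment = modules.labels.rename("module").to_frame()
    if modules.membership is not None:
        assignment = assignment.join(
            modules.membership[["kME", "p_mm", "p_mm_adj"]], how="left"
        )
    path = prefix.with_suffix(".modules.csv")
    assignment.to_csv(path, index_label="interaction")
    written.append(path)
    if modules.eigengenes is not None:
        path = prefix.with_suffix(".eigengenes.csv")
        modules.eigengenes.to_csv(path, index_label="module")
        written.append(path)
    if modules.module_trait is not None:
        path = prefix.with_suffix(".module_trait.csv")
        modules.module_trait.to_csv(path)
        written.append(path)
    return written


def _plain(v):
    try:
        return v.item()
    except AttributeError:
        return v
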