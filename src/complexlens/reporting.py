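"""Run configuration and the two-complex comparison driver.

``run_complex_comparison`` is the batch entry point that, given two
ternary-complex structures and a chain map (which chain is the ligand,
which is IFNλR1, which is IL10Rβ), emits everything the pairwise
comparison needs: per-interface buried-area reports for each complex,
the cross-complex BSA ratio, per-residue fold changes for requested
residues, polar-contact counts and their difference, and the static
receptor-rotation angle. Every numeric output is accompanied by the
parameter values that produced it, because interface areas and contact
counts are convention-sensitive.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import yaml

from .geometry import receptor_rotation_angle
from .interface_analysis import (
    InterfaceReport,
    PolarContactParams,
    SasaParams,
    buried_surface_area,
    residue_bsa_fold_change,
)
from .structure_io import Structure, parse_structure, resolve_selection

__all__ = ["RunConfig", "run_complex_comparison", "write_report"]


class ConfigError(ValueError):
    """Raised for an incomplete or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Declarative description of a two-complex comparison run.

    ``chain_map_a`` / ``chain_map_b`` must map the three roles
    ``ligand``, ``ifnlr1`` and ``il10rb`` to chain ids of the respective
    structure files — the deposited models do not fix chain naming, so
    the mapping is user input.
    """

    structure_a: str
    structure_b: str
    chain_map_a: dict
    chain_map_b: dict
    label_a: str = "complex_a"
    label_b: str = "complex_b"
    sasa: SasaParams = field(default_factory=SasaParams)
    contacts: PolarContactParams = field(default_factory=PolarContactParams)
    align_residue_range: tuple[int, int] | None = None  # common IFNλR1 range
    vertex_residue: tuple[str, int] | None = None  # on il10rb chain, e.g. 82
    probe_residue: tuple[str, int] | None = None  # e.g. 46
    fold_change_residues: list = field(default_factory=list)  # residue keys in A paired with B
    output_dir: str = "."

    REQUIRED_ROLES = ("ligand", "ifnlr1", "il10rb")

    def __post_init__(self):
        for role in self.REQUIRED_ROLES:
            for name, cmap in (("chain_map_a", self.chain_map_a), ("chain_map_b", self.chain_map_b)):
                if role not in cmap:
                    raise ConfigError(f"{name} is missing the {role!r} role")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("sasa", "contacts"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = (SasaParams if key == "sasa" else PolarContactParams)(**raw[key])
        if "align_residue_range" in raw and raw["align_residue_range"] is not None:
            raw["align_residue_range"] = tuple(raw["align_residue_range"])
        for key in ("vertex_residue", "probe_residue"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _interfaces(
    structure: Structure, chain_map: dict, cfg: RunConfig
) -> dict[str, InterfaceReport]:
    out = {}
    for partner in ("ifnlr1", "il10rb"):
        ga = resolve_selection(structure, {"chains": [chain_map["ligand"]], "heavy": True})
        gb = resolve_selection(structure, {"chains": [chain_map[partner]], "heavy": True})
        out[f"ligand:{partner}"] = buried_surface_area(
            structure, ga, gb, cfg.sasa, cfg.contacts
        )
    return out


def _report_dict(rep: InterfaceReport) -> dict:
    return {
        "bsa_total_twosided_A2": rep.bsa_total_twosided,
        "bsa_total_onesided_A2": rep.bsa_total_onesided,
        "n_polar_contacts": rep.n_polar_contacts,
        "polar_contacts": [
            {"a": c.label_a, "b": c.label_b, "distance_A": round(c.distance, 3)}
            for c in rep.polar_contacts
        ],
        "per_residue_bsa_A2": {
            f"{k[0]}:{k[1]}{k[2]}": round(v, 2)
            for k, v in sorted(rep.per_residue_bsa.items())
            if v > 0
        },
        "per_residue_burial_fraction": {
            f"{k[0]}:{k[1]}{k[2]}": round(v, 4)
            for k, v in sorted(rep.per_residue_burial_fraction.items())
            if v > 0
        },
    }


def run_complex_comparison(config: RunConfig) -> dict:
    """Full pairwise comparison of two ternary complexes; returns the report."""
    st_a = (
        config.structure_a
        if isinstance(config.structure_a, Structure)
        else parse_structure(config.structure_a)
    )
    st_b = (
        config.structure_b
        if isinstance(config.structure_b, Structure)
        else parse_structure(config.structure_b)
    )

    reports_a = _interfaces(st_a, config.chain_map_a, config)
    reports_b = _interfaces(st_b, config.chain_map_b, config)

    ratio = {}
    for key in reports_a:
        num = reports_a[key].bsa_total_twosided
        den = reports_b[key].bsa_total_twosided
        ratio[key] = num / den if den > 0 else math.inf

    contact_diff = {
        key: reports_a[key].n_polar_contacts - reports_b[key].n_polar_contacts
        for key in reports_a
    }

    folds = {}
    if config.fold_change_residues:
        rep_x = reports_a["ligand:ifnlr1"]
        rep_y = reports_b["ligand:ifnlr1"]
        pairs = [tuple(map(tuple, pair)) for pair in config.fold_change_residues]
        for pair, fc in residue_bsa_fold_change(rep_x, rep_y, pairs).items():
            label = f"{pair[0][0]}:{pair[0][1]}|{pair[1][0]}:{pair[1][1]}"
            folds[label] = {"fold": fc.fold if not fc.infinite else None, "infinite": fc.infinite}

    rotation = None
    if config.vertex_residue and config.probe_residue:
        expr_a: dict = {"chains": [config.chain_map_a["ifnlr1"]], "calpha": True}
        expr_b: dict = {"chains": [config.chain_map_b["ifnlr1"]], "calpha": True}
        if config.align_residue_range:
            expr_a["residues"] = [config.align_residue_range]
            expr_b["residues"] = [config.align_residue_range]
        sel_a = resolve_selection(st_a, expr_a)
        sel_b = resolve_selection(st_b, expr_b)
        vert_a = (config.chain_map_a["il10rb"], config.vertex_residue[-1])
        probe_a = (config.chain_map_a["il10rb"], config.probe_residue[-1])
        rotation = receptor_rotation_angle(
            st_a, st_b, sel_a, sel_b, vert_a, probe_a
        )

    return {
        "parameters": {
            "sasa": dataclasses.asdict(config.sasa),
            "contacts": {
                **dataclasses.asdict(config.contacts),
                "donor_acceptor_elements": sorted(config.contacts.donor_acceptor_elements),
            },
            "align_residue_range": config.align_residue_range,
            "vertex_residue": config.vertex_residue,
            "probe_residue": config.probe_residue,
        },
        config.label_a: {k: _report_dict(v) for k, v in reports_a.items()},
        config.label_b: {k: _report_dict(v) for k, v in reports_b.items()},
        "comparison": {
            "bsa_ratio_a_over_b": ratio,
            "polar_contact_difference_a_minus_b": contact_diff,
            "per_residue_fold_changes": folds,
            "receptor_rotation_deg": rotation,
        },
    }


def write_report(report: dict, output_dir: str, stem: str = "comparison") -> None:
    """Write the JSON report and a per-residue TSV table."""
    os.makedirs(output_dir, exist_ok=True)
    with open(os.path.join(output_dir, f"{stem}.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    rows = ["complex\tinterface\tresidue\tbsa_A2\tburial_fraction"]
    for label, interfaces in report.items():
        if label in ("parameters", "comparison"):
            continue
        for iface, rep in interfaces.items():
            fracs = rep["per_residue_burial_fraction"]
            for res, bsa in rep["per_residue_bsa_A2"].items():
                rows.append(
                    f"{label}\t{iface}\t{res}\t{bsa}\t{fracs.get(res, 0.0)}"
                )
    with open(os.path.join(output_dir, f"{stem}.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
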