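"""Case-study fixture data: evidence tables for the three worked examples
(manure reuse in horticulture, insect rearing on side streams, short-chain
wheat), plus the wheat survey summary targets and printed verdicts.

Profiles are built in code and serialised through the registry writer, so the
shipped CSV fixtures are round-trip products of the same schema the loader
validates.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import (
    HazardLevel,
    HazardProfile,
    OccurrenceEvidence,
    PersistenceEvidence,
    SeverityEvidence,
    TransferEvidence,
    save_ruleset,
    load_ruleset,
    write_hazard_registry,
)
from .combine import (
    ACCUMULATION_PRESENCE_RULES,
    ENVIRONMENT_PRESENCE_RULES,
    PRIORITY_RULES,
)
from .pool_synth import PoolSummaryTargets

L, M, H = HazardLevel.LOW, HazardLevel.MEDIUM, HazardLevel.HIGH

# ---------------------------------------------------------------------------
# Case 1: animal manure in horticulture
# ---------------------------------------------------------------------------

# Average antibiotic concentrations in raw manure (ng/g dm), per manure type.
MANURE_OCCURRENCE_NG_G = {
    "(fluoro)quinolones": {"raw cattle manure": 7900.0, "raw poultry manure": 92696.0,
                           "raw swine manure": 12099.0},
    "macrolides": {"raw cattle manure": 40.0, "raw poultry manure": 3836.0,
                   "raw swine manure": 6927.0},
    "sulphonamides": {"raw cattle manure": 1277.0, "raw poultry manure": 10591.0,
                      "raw swine manure": 6277.0},
    "tetracyclines": {"raw cattle manure": 40805.0, "raw poultry manure": 30166.0,
                      "raw swine manure": 89639.0},
}

# Group averages over manure types (the occurrence basis for the antibiotic
# classification; see the decisions ledger on the collapse policy).
MANURE_OCCURRENCE_MEAN_NG_G = {
    "(fluoro)quinolones": 37566.0,
    "macrolides": 3601.0,
    "sulphonamides": 6048.0,
    "tetracyclines": 53537.0,
}

# Average pathogen concentrations in raw manure (cfu/g dm), per manure type.
MANURE_OCCURRENCE_CFU_G = {
    "E. coli": {"raw cattle manure": 1.3e8, "raw poultry manure": 2.2e7,
                "raw swine manure": 4.7e4},
    "Salmonella": {"raw cattle manure": 3.1e5, "raw poultry manure": 1.4e4,
                   "raw swine manure": 3.7e3},
}

# Average DT50 (days) for antibiotic groups in manure types.
DT50_MANURE_DAYS = {
    "(fluoro)quinolones": {"manure:cattle solid": 564.0, "manure:cattle semi-solid": 226.0,
                           "manure:cattle liquid": 82.0, "manure:pig": 75.0,
                           "manure:broiler": 121.0},
    "macrolides": {"manure:cattle solid": 29.0, "manure:cattle semi-solid": 47.0,
                   "manure:cattle liquid": 9.0, "manure:pig": 50.0, "manure:broiler": 61.0},
    "sulphonamides": {"manure:cattle solid": 1.0, "manure:cattle semi-solid": 3.0,
                      "manure:cattle liquid": 12.0, "manure:pig": 2.0, "manure:broiler": 3.0},
    "tetracyclines": {"manure:cattle solid": 76.0, "manure:cattle semi-solid": 57.0,
                      "manure:cattle liquid": 32.0, "manure:pig": 14.0, "manure:broiler": 33.0},
}

# Average DT50 (days) for antibiotic groups in two soil types.
DT50_SOIL_DAYS = {
    "(fluoro)quinolones": {"soil:sand": 182.0, "soil:clay": 97.0},
    "macrolides": {"soil:sand": 56.0, "soil:clay": 73.0},
    "sulphonamides": {"soil:sand": 1.0, "soil:clay": 1.0},
    "tetracyclines": {"soil:sand": 9.0, "soil:clay": 1.0},
}

# log10 K_OC per antibiotic group (plant-uptake mobility).
LOG_KOC = {
    "(fluoro)quinolones": 2.9,
    "macrolides": 2.0,
    "sulphonamides": 0.5,
    "tetracyclines": 3.0,
}

# Chronic-toxicity guidance values (JECFA ADIs, ug/kg bw/day) and antibiotic
# choice class (2/3 = second/third-choice antibiotic -> high resistance concern).
ANTIBIOTIC_SEVERITY = {
    "(fluoro)quinolones": {"adi": 2.0, "choice": 3},
    "macrolides": {"adi": 30.0, "choice": 2},
    "sulphonamides": {"adi": 50.0, "choice": 1},
    "tetracyclines": {"adi": 30.0, "choice": 2},
}

# Field die-off (days per 1-log reduction) and the 60-day pre-harvest
# waiting time for raw-manure-amended leafy greens.
PATHOGEN_LOG_REDUCTION_DAYS = {"E. coli": 12.6, "Salmonella": 15.9}
WAITING_TIME_DAYS = 60.0

# Pathogen disease burden (DALY/case); E. coli scored via STEC O157.
PATHOGEN_DALY = {"E. coli": 0.065, "Salmonella": 0.039}

# Full pathogen severity reference list (DALY/case -> printed class).
PATHOGEN_SEVERITY_TABLE = {
    "Bacillus cereus": (0.0023, L),
    "Clostridium perfringens": (0.0032, L),
    "Cryptosporidium spp": (0.0024, L),
    "Giardia spp": (0.0018, L),
    "norovirus": (0.0026, L),
    "Rotavirus": (0.0054, L),
    "Staphylococcus aureus": (0.0026, L),
    "Campylobacter": (0.034, M),
    "Hepatitis A virus": (0.161, H),
    "Hepatitis E virus": (0.434, H),
    "STEC O157": (0.065, M),
    "Salmonella spp": (0.039, M),
    "Listeria monocytogenes": (1.161, H),
    "Toxoplasma gondii": (3.173, H),
}

# Expected case-1 level columns (occurrence, persistence-combined, transfer,
# presence, severity, priority).
CASE1_EXPECTED = {
    "(fluoro)quinolones": {"occurrence": H, "persistence": H, "transfer": L,
                           "presence": H, "severity": H, "priority": H},
    "macrolides": {"occurrence": L, "persistence": M, "transfer": L,
                   "presence": L, "severity": M, "priority": L},
    "sulphonamides": {"occurrence": L, "persistence": L, "transfer": H,
                      "presence": L, "severity": L, "priority": L},
    "tetracyclines": {"occurrence": H, "persistence": M, "transfer": L,
                      "presence": M, "severity": M, "priority": M},
    "E. coli": {"occurrence": H, "persistence": L, "transfer": M,
                "presence": M, "severity": M, "priority": M},
    "Salmonella": {"occurrence": L, "persistence": L, "transfer": M,
                   "presence": L, "severity": M, "priority": L},
}


def case1_profiles() -> list[HazardProfile]:
    profiles: list[HazardProfile] = []
    for group in ("(fluoro)quinolones", "macrolides", "sulphonamides", "tetracyclines"):
        sev = ANTIBIOTIC_SEVERITY[group]
        profiles.append(HazardProfile(
            hazard_id=group, hazard_class="chemical", route="environment",
            occurrence=(OccurrenceEvidence(
                kind="chemical_concentration",
                value=MANURE_OCCURRENCE_MEAN_NG_G[group],
                matrix="manure (global average)"),),
            persistence=PersistenceEvidence(
                dt50_days_by_compartment={**DT50_MANURE_DAYS[group], **DT50_SOIL_DAYS[group]}),
            transfer=TransferEvidence(kind="log_koc", value=LOG_KOC[group]),
            severity=SeverityEvidence(kind="antibiotic", hbgv_value=sev["adi"],
                                      hbgv_basis="per_day",
                                      antibiotic_choice_class=sev["choice"]),
        ))
    for pathogen in ("E. coli", "Salmonella"):
        if pathogen == "Salmonella":
            # the worked verdict classifies persistence Low although
            # 60 d / 15.9 d-per-log = 3.77 logs misses the 4-log bound;
            # the fixture ships the verdict as an assigned-level override
            persistence = PersistenceEvidence(assigned_level=L)
        else:
            persistence = PersistenceEvidence(
                log_reduction_days=PATHOGEN_LOG_REDUCTION_DAYS[pathogen],
                waiting_time_days=WAITING_TIME_DAYS)
        profiles.append(HazardProfile(
            hazard_id=pathogen, hazard_class="microbial", route="environment",
            occurrence=tuple(OccurrenceEvidence(kind="microbial_concentration",
                                                value=v, matrix=m)
                             for m, v in MANURE_OCCURRENCE_CFU_G[pathogen].items()),
            persistence=persistence,
            transfer=TransferEvidence(kind="assigned_level", level=M),
            severity=SeverityEvidence(kind="microbial",
                                      daly_per_case=PATHOGEN_DALY[pathogen]),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Case 2: insect (black soldier fly) rearing on side streams
# ---------------------------------------------------------------------------

# Occurrence levels per substrate, BAF and guidance value per hazard.
CASE2_HAZARDS = {
    "dioxins & PCBs": {"household": L, "manure": M, "baf": 2.0,
                       "hbgv": 2e-6, "basis": "per_week"},
    "tetracyclines/veterinary drugs": {"household": L, "manure": H, "baf": 0.0,
                                       "hbgv": 30.0, "basis": "per_day"},
    "pesticides": {"household": L, "manure": L, "baf": 0.0,
                   "hbgv": 50.0, "basis": "per_day"},
    "cadmium": {"household": M, "manure": L, "baf": 20.0,
                "hbgv": 2.5, "basis": "per_week"},
    "lead": {"household": H, "manure": L, "baf": 2.3,
             "hbgv": 0.63, "basis": "per_day"},
    "aflatoxin B1": {"household": L, "manure": L, "baf": 0.0,
                     "hbgv": 0.4, "basis": "per_day"},
    "deoxynivalenol": {"household": L, "manure": L, "baf": 0.0,
                       "hbgv": 1.0, "basis": "per_day"},
}

# Published single-priority column; differs from the strict matrix output for
# dioxins (printed M, matrix H) and the two mycotoxins (printed L, matrix M).
CASE2_PRINTED_PRIORITY = {
    "dioxins & PCBs": M,
    "tetracyclines/veterinary drugs": L,
    "pesticides": L,
    "cadmium": H,
    "lead": H,
    "aflatoxin B1": L,
    "deoxynivalenol": L,
}

CASE2_STRICT_PRIORITY = {
    "household": {"dioxins & PCBs": H, "tetracyclines/veterinary drugs": L,
                  "pesticides": L, "cadmium": H, "lead": H,
                  "aflatoxin B1": M, "deoxynivalenol": M},
    "manure": {"dioxins & PCBs": H, "tetracyclines/veterinary drugs": L,
               "pesticides": L, "cadmium": H, "lead": H,
               "aflatoxin B1": M, "deoxynivalenol": M},
}


def case2_profiles(substrate: str) -> list[HazardProfile]:
    """One profile per hazard for one substrate ('household' or 'manure')."""
    if substrate not in ("household", "manure"):
        raise ValueError(f"unknown substrate {substrate!r}")
    matrix = "household waste" if substrate == "household" else "manure"
    profiles = []
    for hazard_id, d in CASE2_HAZARDS.items():
        profiles.append(HazardProfile(
            hazard_id=hazard_id, hazard_class="chemical", route="accumulation",
            occurrence=(OccurrenceEvidence(kind="assigned_level",
                                           level=d[substrate], matrix=matrix),),
            transfer=TransferEvidence(kind="bioaccumulation_factor", value=d["baf"]),
            severity=SeverityEvidence(kind="chemical", hbgv_value=d["hbgv"],
                                      hbgv_basis=d["basis"]),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Case 3: short-chain vs conventional wheat
# ---------------------------------------------------------------------------

# Wheat survey summary statistics (ug/kg; 293 commercial fields).
TABLE_WHEAT_TARGETS = {
    "DON": PoolSummaryTargets(median=60.0, mean=411.0, max=15400.0,
                              frac_above_limit=0.061, limit=1250.0, floor=25.0),
    "ZEA": PoolSummaryTargets(median=25.0, mean=65.0, max=2000.0,
                              frac_above_limit=0.069, limit=100.0, floor=25.0),
    "T-2 and HT-2": PoolSummaryTargets(median=10.0, mean=11.7, max=66.0,
                                       frac_above_limit=0.0, limit=100.0, floor=10.0),
}

WHEAT_LIMIT_KIND = {"DON": "maximum_limit", "ZEA": "maximum_limit",
                    "T-2 and HT-2": "guidance"}

# Printed scenario summaries (min, median, mean, max, % > limit).
WHEAT_SHORT_CHAIN_PRINTED = {
    "DON": (25.0, 60.0, 411.0, 15400.0, 6.2),
    "ZEA": (25.0, 25.0, 63.0, 2000.0, 6.7),
    "T-2 and HT-2": (10.0, 10.0, 12.0, 38.0, 0.0),
}
WHEAT_CONVENTIONAL_PRINTED = {
    "DON": (45.0, 221.0, 409.0, 5257.0, 7.5),
    "ZEA": (25.0, 33.0, 65.0, 1001.0, 13.7),
    "T-2 and HT-2": (10.0, 11.0, 12.0, 66.0, 0.0),
}

# Milling processing factors, white flour (range -> point value at mid-range).
PROCESSING_FACTOR_RANGES = {
    "DON": (0.5, 0.8),
    "ZEA": (0.1, 0.9),
    "T-2 and HT-2": (0.2, 0.4),
}

# Group TDIs (ug/kg bw/day).
MYCOTOXIN_TDI = {"DON": 1.0, "ZEA": 0.25, "T-2 and HT-2": 0.02}

# Short-chain exceedance fractions feeding the occurrence indicator.
CASE3_EXCEEDANCE = {"DON": 0.062, "ZEA": 0.067, "T-2 and HT-2": 0.0}

# Expected case-3 level columns under the strict matrices.  The published
# narrative calls T-2/HT-2 "medium priority" but the printed table and the
# matrices both give High via presence (L,H,H) -> M and priority (M,H) -> H.
CASE3_EXPECTED = {
    "DON": {"occurrence": H, "persistence": H, "transfer": H,
            "presence": H, "severity": H, "priority": H},
    "ZEA": {"occurrence": H, "persistence": H, "transfer": H,
            "presence": H, "severity": H, "priority": H},
    "T-2 and HT-2": {"occurrence": L, "persistence": H, "transfer": H,
                     "presence": M, "severity": H, "priority": H},
}


def case3_profiles() -> list[HazardProfile]:
    profiles = []
    for analyte, frac in CASE3_EXCEEDANCE.items():
        profiles.append(HazardProfile(
            hazard_id=analyte, hazard_class="chemical", route="environment",
            occurrence=(OccurrenceEvidence(kind="exceedance_fraction", value=frac,
                                           matrix="wheat at harvest"),),
            persistence=PersistenceEvidence(assigned_level=H),
            transfer=TransferEvidence(kind="assigned_level", level=H),
            severity=SeverityEvidence(kind="chemical", hbgv_value=MYCOTOXIN_TDI[analyte],
                                      hbgv_basis="per_day"),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_case_fixtures(outdir: "str | Path") -> list[Path]:
    """Write all case-study registries and default configs as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, profiles in [
        ("case1_manure_horticulture.csv", case1_profiles()),
        ("case2_insects_household_waste.csv", case2_profiles("household")),
        ("case2_insects_manure.csv", case2_profiles("manure")),
        ("case3_wheat_mycotoxins.csv", case3_profiles()),
    ]:
        path = outdir / name
        write_hazard_registry(profiles, path)
        written.append(path)

    rules_path = outdir / "default_rules.yaml"
    save_ruleset(load_ruleset(None), rules_path)
    written.append(rules_path)

    matrices_path = outdir / "default_matrices.yaml"
    matrices_path.write_text(yaml.safe_dump({
        "presence_environment": ENVIRONMENT_PRESENCE_RULES,
        "presence_accumulation": ACCUMULATION_PRESENCE_RULES,
        "priority": PRIORITY_RULES,
    }, sort_keys=False))
    written.append(matrices_path)

    targets_path = outdir / "wheat_pool_targets.yaml"
    targets_path.write_text(yaml.safe_dump(
        {name: t.model_dump() for name, t in TABLE_WHEAT_TARGETS.items()},
        sort_keys=False))
    written.append(targets_path)
    return written
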