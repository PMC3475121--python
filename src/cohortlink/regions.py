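"""Country -> WHO region lookup and ethnicity grouping used by harmonization.

The region vocabulary follows the WHO's six regions plus "Not Known".  The
table below covers the countries of birth that occur in UK HIV cohorts with
any frequency; ``resolve_region_of_birth`` treats countries not listed here
as unknown (with a warning) rather than failing.
"""
from __future__ import annotations

REGIONS = (
    "African",
    "European",
    "Region of the Americas",
    "Eastern Mediterranean",
    "South-East Asia",
    "Western Pacific",
    "Not Known",
)

WHO_REGIONS: dict[str, str] = {
    # African region
    "Nigeria": "African",
    "Ghana": "African",
    "Uganda": "African",
    "Kenya": "African",
    "Zimbabwe": "African",
    "Zambia": "African",
    "Malawi": "African",
    "South Africa": "African",
    "Cameroon": "African",
    "Ivory Coast": "African",
    "Congo": "African",
    "Democratic Republic of the Congo": "African",
    "Ethiopia": "African",
    "Eritrea": "African",
    "Tanzania": "African",
    "Rwanda": "African",
    "Burundi": "African",
    "Sierra Leone": "African",
    "Angola": "African",
    "Botswana": "African",
    "Gambia": "African",
    "Senegal": "African",
    "Togo": "African",
    "Mozambique": "African",
    # European region
    "United Kingdom": "European",
    "Ireland": "European",
    "France": "European",
    "Portugal": "European",
    "Spain": "European",
    "Italy": "European",
    "Germany": "European",
    "Poland": "European",
    "Netherlands": "European",
    "Romania": "European",
    "Russia": "European",
    "Ukraine": "European",
    # Region of the Americas
    "Jamaica": "Region of the Americas",
    "Barbados": "Region of the Americas",
    "Trinidad and Tobago": "Region of the Americas",
    "Guyana": "Region of the Americas",
    "Brazil": "Region of the Americas",
    "Colombia": "Region of the Americas",
    "United States": "Region of the Americas",
    "Canada": "Region of the Americas",
    # Eastern Mediterranean region (WHO places Somalia and Pakistan here)
    "Somalia": "Eastern Mediterranean",
    "Pakistan": "Eastern Mediterranean",
    "Egypt": "Eastern Mediterranean",
    "Sudan": "Eastern Mediterranean",
    "Morocco": "Eastern Mediterranean",
    "Iran": "Eastern Mediterranean",
    # South-East Asia region
    "India": "South-East Asia",
    "Thailand": "South-East Asia",
    "Bangladesh": "South-East Asia",
    "Sri Lanka": "South-East Asia",
    "Myanmar": "South-East Asia",
    "Indonesia": "South-East Asia",
    # Western Pacific region
    "China": "Western Pacific",
    "Philippines": "Western Pacific",
    "Vietnam": "Western Pacific",
    "Malaysia": "Western Pacific",
    "Japan": "Western Pacific",
    "Australia": "Western Pacific",
}

# Top-level groups for the ethnicity-conflict rule.  A *strong* discrepancy
# (black vs white) voids the value; any other disagreement — including
# black-other vs other — is "somewhat discrepant" and defers to the clinic
# cohort, whose ethnicity is reported repeatedly over years of follow-up.
ETHNICITY_GROUPS: dict[str, str] = {
    "black-African": "black",
    "black-Caribbean": "black",
    "black-other": "black",
    "white": "white",
    "other": "other",
}

# Pairs of top-level groups whose disagreement is irreconcilable.
STRONG_CONFLICTS: frozenset[frozenset[str]] = frozenset(
    {frozenset({"black", "white"})}
)
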