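"""Registry of pathway-to-care node types.

A *node* is one interaction on a patient's help-seeking pathway, either with
a community caregiver (a family member, a police officer, a teacher, the
patient acting on their own behalf) or with a clinical caregiver (an
emergency department, an inpatient unit, an outpatient mental-health clinic,
...). The catalogue below reflects the stakeholder types a regional
first-episode-psychosis service typically encounters; cohorts that need
additional types must register them here via :func:`register_node_type`
rather than use free-text labels, so that summary tables never silently
absorb typos into an "Other" bucket.
"""

from __future__ import annotations

from enum import Enum


class Category(str, Enum):
    COMMUNITY = "community"
    CLINICAL = "clinical"


#: label -> category. Frozen default catalogue: 5 community, 9 clinical.
NODE_TYPES: dict[str, Category] = {
    # community caregivers
    "Family": Category.COMMUNITY,
    "Self": Category.COMMUNITY,          # patient initiated the next step alone
    "Police": Category.COMMUNITY,
    "Education": Category.COMMUNITY,     # teacher or school counsellor
    "OtherCommunity": Category.COMMUNITY,
    # clinical caregivers
    "ED": Category.CLINICAL,             # emergency department
    "Inpt": Category.CLINICAL,           # inpatient psychiatric admission
    "Outpt": Category.CLINICAL,          # outpatient mental health
    "IOP": Category.CLINICAL,            # intensive outpatient program
    "Acute": Category.CLINICAL,          # walk-in / urgent-care evaluation
    "PCP": Category.CLINICAL,            # primary care provider
    "Mobile": Category.CLINICAL,         # mobile crisis evaluation
    "OtherMH": Category.CLINICAL,        # other mental-health setting
    "OtherMed": Category.CLINICAL,       # other non-psychiatric medical care
}

#: virtual terminals used by the transition graph; never valid encounter types
ONSET = "Onset"
STEP = "STEP"


def category_of(node_type: str) -> Category:
    """Category of a registered node type; raises KeyError with the bad label."""
    try:
        return NODE_TYPES[node_type]
    except KeyError:
        raise KeyError(
            f"unknown node_type {node_type!r}; register it with "
            "ptcdelay.nodes.register_node_type before loading the cohort"
        ) from None


def register_node_type(label: str, category: Category | str) -> None:
    """Extend the node-type catalogue for a cohort with extra caregiver types."""
    if label in (ONSET, STEP):
        raise ValueError(f"{label!r} is reserved for graph terminals")
    cat = Category(category)
    existing = NODE_TYPES.get(label)
    if existing is not None and existing is not cat:
        raise ValueError(f"{label!r} already registered as {existing.value}")
    NODE_TYPES[label] = cat


def community_types() -> list[str]:
    return [t for t, c in NODE_TYPES.items() if c is Category.COMMUNITY]


def clinical_types() -> list[str]:
    return [t for t, c in NODE_TYPES.items() if c is Category.CLINICAL]
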