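"""Label inventories and placeholder strings.

Two annotation layers cover each document: a PII layer with thirteen classes
of direct and indirect identifiers, and a clinical layer with three entity
classes.  PII spans must not overlap each other; clinical spans may nest.
"""

from __future__ import annotations

PII_LABELS: tuple[str, ...] = (
    "FirstName",
    "LastName",
    "Occupation",
    "Company",
    "Location",
    "FullDate",
    "DatePart",
    "HealthCareUnit",
    "PersonalID",
    "ID",
    "PhoneNumber",
    "Email",
    "Age",
)

CLINICAL_LABELS: tuple[str, ...] = ("Disease", "BodyPart", "Medication")

LAYER_PII = "pii"
LAYER_CLINICAL = "clinical"

#: layer membership of every known label
LABEL_LAYER: dict[str, str] = {
    **{lab: LAYER_PII for lab in PII_LABELS},
    **{lab: LAYER_CLINICAL for lab in CLINICAL_LABELS},
}

#: bracketed class-name placeholders used by the masking procedure
DEFAULT_PLACEHOLDERS: dict[str, str] = {
    "FirstName": "[First Name]",
    "LastName": "[Last Name]",
    "Occupation": "[Occupation]",
    "Company": "[Company]",
    "Location": "[Location]",
    "FullDate": "[Full Date]",
    "DatePart": "[Date Part]",
    "HealthCareUnit": "[Health Care Unit]",
    "PersonalID": "[Personal ID]",
    "ID": "[ID]",
    "PhoneNumber": "[Phone Number]",
    "Email": "[Email]",
    "Age": "[Age]",
}

SUBCORPORA = ("accident", "disease")
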