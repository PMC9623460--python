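"""Code systems shared by the synthetic-data generator and the case book.

Real deployments supply flat concept-set files mapping their local
terminologies; the bundled study cases use a miniature ATC-like drug
vocabulary and a local vocabulary for anesthesia milestones, monitor
signals and laboratory results.  Everything here is plain data — one place
to look up which codes the simulator emits and the case definitions select.
"""

from __future__ import annotations

# vocabularies
ATC = "ATC"
LOCAL = "LOCAL"

# monitor / laboratory measurement concepts
PAO2 = "PAO2"          # partial pressure of oxygen, mm Hg
MAP = "MAP"            # mean arterial pressure, mm Hg
SAP = "SAP"            # systolic arterial pressure, mm Hg
HEART_RATE = "HR"      # beats per minute
TIDAL_VOLUME = "TV"    # end-tidal volume, mL
INR = "INR"            # international normalized ratio, dimensionless

# anesthesia milestone event concepts (procedure_occurrence rows)
OR_ARRIVAL = "or_arrival"
INDUCTION = "induction"
HYPNOTIC = "hypnotic"
INTUBATION = "intubation"
VENTILATION = "ventilation"
INCISION = "incision"
BIRTH = "birth"
ANESTHESIA_START = "anesthesia_start"
ANESTHESIA_END = "anesthesia_end"
SPIROMETRY = "spirometry"  # functional respiratory exploration

#: candidate concepts documenting the start of anesthesia, highest expert
#: priority first (the same procedure start may be recorded four ways).
ANESTHESIA_START_PRIORITY = (INDUCTION, HYPNOTIC, INTUBATION, VENTILATION)

# drug codes (miniature ATC)
ATROPINE = "A03BA01"

#: potentially inappropriate medications (Laroche-style PIM list)
LAROCHE_CODES = (
    "N05BA01", "N05BA04", "N05BA06", "N05CD03", "A03AB05", "N06AA09",
)
#: everyday distractor drugs outside every study set
DISTRACTOR_CODES = ("C09AA01", "A02BC01", "B01AC06")

#: vitamin K antagonists, mapped to the wider category "VKA"
VKA_CODES = ("B01AA03", "B01AA04")
VKA_CATEGORY = "VKA"
#: interacting drugs of one potentiation DDI rule, mapped to one category
DDI_PARTNER_CODES = ("J01EE01", "J01EC02")
DDI_PARTNER_CATEGORY = "DDI_SULFONAMIDE"

# suspected-COPD drug classes
BRONCHODILATOR_CODES = ("R03AC02", "R03BB04")
RESP_ANTIBIOTIC_CODES = ("J01CA04", "J01FA09", "J01AA02")
NICOTINIC_CODES = ("N07BA01",)
COPD_SPECIFIC_CODES = BRONCHODILATOR_CODES + RESP_ANTIBIOTIC_CODES + NICOTINIC_CODES

# laboratory thresholds of the DDI response rules
INR_HIGH = 5.0   # VKA potentiation: at least one INR >= 5
INR_LOW = 1.5    # VKA inhibition: at least one INR <= 1.5
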