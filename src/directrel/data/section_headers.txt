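# Section header lexicon: line-initial, colon-terminated headers of
# discharge summaries.  One header name per line; matching is
# case-insensitive on whole header lines ending with ':'.
HISTORY OF PRESENT ILLNESS
PAST MEDICAL HISTORY
HOSPITAL COURSE
BRIEF HOSPITAL COURSE
MEDICATIONS
DISCHARGE MEDICATIONS
ADMISSION MEDICATIONS
PHYSICAL EXAMINATION
LABORATORY DATA
ALLERGIES
SOCIAL HISTORY
FAMILY HISTORY
REVIEW OF SYSTEMS
ASSESSMENT AND PLAN
DISCHARGE DIAGNOSIS
CHIEF COMPLAINT
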