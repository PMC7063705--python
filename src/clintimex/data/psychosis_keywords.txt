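# Stand-in psychosis symptom keyword list (26 terms).
# The clinically curated source list is access-controlled; replace this
# file (or pass --keywords) to use your own. Matching is whole-word and
# case-insensitive by default.
hallucination
hallucinations
hallucinating
auditory hallucinations
visual hallucinations
hearing voices
voices
delusion
delusions
delusional
paranoia
paranoid
psychosis
psychotic
thought disorder
disordered thinking
thought broadcasting
thought insertion
ideas of reference
persecutory
grandiose
unusual beliefs
suspiciousness
derealisation
depersonalisation
catatonia
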