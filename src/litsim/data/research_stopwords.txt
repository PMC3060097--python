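# Curated list of frequent, low-content words of research prose (a synthetic
# reconstruction of the kind of institutional stoplist used alongside the
# MEDLINE list; override with your own file via configuration).
aim
aims
analysis
analyses
approach
associated
association
background
based
case
cases
compared
comparison
conclusion
conclusions
data
decrease
decreased
demonstrate
demonstrated
determine
determined
difference
differences
different
effect
effects
evaluate
evaluated
evaluation
finding
findings
group
groups
high
higher
important
increase
increased
investigate
investigated
large
level
levels
low
lower
measure
measured
measures
method
methods
new
number
objective
objectives
observed
one
patient
patients
performed
potential
present
purpose
rate
rates
report
reported
respectively
result
results
role
significance
significant
small
studies
study
suggest
suggested
suggests
three
time
total
two
use
used
using
well
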