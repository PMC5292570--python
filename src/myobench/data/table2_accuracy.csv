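# Five-task myoelectric pattern-recognition accuracies (percent) per subject
# and electrode condition (wet Ag/AgCl vs PPy fabric electrodes).
# 6 able-bodied subjects, 5 tasks, 2 electrode conditions.
task,subject,condition,accuracy
relax,A,wet,100
relax,A,ppy,100
relax,B,wet,99.3
relax,B,ppy,100
relax,C,wet,99.5
relax,C,ppy,100
relax,D,wet,99.7
relax,D,ppy,99.8
relax,E,wet,100
relax,E,ppy,99.2
relax,F,wet,99.8
relax,F,ppy,100
close,A,wet,87.2
close,A,ppy,89.2
close,B,wet,86.7
close,B,ppy,82.5
close,C,wet,98.2
close,C,ppy,90.8
close,D,wet,86.3
close,D,ppy,85.7
close,E,wet,88.8
close,E,ppy,90.2
close,F,wet,89.2
close,F,ppy,87.2
open,A,wet,78.3
open,A,ppy,93.5
open,B,wet,87.7
open,B,ppy,83.5
open,C,wet,82.8
open,C,ppy,83.2
open,D,wet,82.1
open,D,ppy,84.5
open,E,wet,86.2
open,E,ppy,87.9
open,F,wet,87.5
open,F,ppy,74.3
flexion,A,wet,87.8
flexion,A,ppy,74.7
flexion,B,wet,90.0
flexion,B,ppy,86.5
flexion,C,wet,93.7
flexion,C,ppy,96.5
flexion,D,wet,85.4
flexion,D,ppy,87.2
flexion,E,wet,93.5
flexion,E,ppy,86.7
flexion,F,wet,77.7
flexion,F,ppy,82.8
extension,A,wet,89.7
extension,A,ppy,91.5
extension,B,wet,76.8
extension,B,ppy,69.2
extension,C,wet,83.2
extension,C,ppy,89.7
extension,D,wet,79.2
extension,D,ppy,78.8
extension,E,wet,85.7
extension,E,ppy,89.4
extension,F,wet,85.5
extension,F,ppy,88.3
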