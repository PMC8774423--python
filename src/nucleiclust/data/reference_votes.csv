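feature,chi2,fisher_score,info_gain,anova,rfe,permutation_importance,boruta
total intra-cluster total MST distance,True,True,True,True,True,True,True
total intra-cluster nucleus to nucleus maximum distance,True,True,True,True,True,True,True
inter-cluster centroid to centroid total distance,True,False,True,True,True,True,True
inter-cluster total MST distance,True,True,True,True,True,False,True
number of clusters,True,True,True,True,True,False,True
total intra-cluster maximum MST distance,True,True,True,True,True,False,True
average intra-cluster nucleus to nucleus minimum distance,False,True,True,True,True,False,True
average intra-cluster nucleus to nucleus maximum distance,False,True,True,True,True,False,True
average intra-cluster maximum MST distance,False,True,True,True,True,False,True
average cluster area,True,True,False,False,True,True,True
total intra-cluster nucleus to nucleus total distance,True,False,False,True,True,True,True
total intra-cluster minimum MST distance,True,True,True,True,False,False,True
total intra-cluster nucleus to nucleus minimum distance,True,True,True,True,False,False,True
inter-cluster maximum MST distance,True,True,False,False,True,False,True
average intra-cluster total MST distance,False,True,True,False,True,False,True
average intra-cluster minimum MST distance,False,True,True,True,False,False,True
total cluster area,True,False,False,False,False,True,True
inter-cluster average MST distance,False,False,True,True,False,False,True
average intra-cluster nucleus to nucleus average distance,False,False,True,True,False,False,True
inter-cluster centroid to centroid average distance,False,True,False,False,True,False,False
minimum area of a cluster,True,False,False,False,True,False,False
average intra-cluster nucleus to nucleus total distance,True,False,False,False,False,False,True
inter-cluster centroid to centroid minimum distance,False,False,False,False,False,False,True
inter-cluster centroid to centroid maximum distance,False,False,False,False,False,False,True
maximum area of a cluster,True,False,False,False,False,False,False
inter-cluster minimum MST distance,False,False,False,False,False,False,True
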